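# Cohort design: healthy pancreatic parenchyma without (n=9) vs with (n=8)
# neoadjuvant chemotherapy.  Concentrations in nmol/mg wet tissue.
# group PP_noNAC: n=9 tissue=PP chemo=no survival=unknown
# group PP_NAC: n=8 tissue=PP chemo=yes survival=unknown
metabolite,PP_noNAC_mean,PP_noNAC_sd,PP_NAC_mean,PP_NAC_sd
ascorbate,0.3488,0.2191,0.3592,0.1671
aspartate,0.7577,0.3284,0.6730,0.1776
choline,1.5580,0.5921,1.7649,0.7624
creatine,1.7371,0.9568,1.7760,0.6579
ethanolamine,0.9314,0.4502,1.1115,0.5408
glutamate,2.9830,0.8698,2.3800,0.4264
glycerol,8.1840,7.3988,8.2990,7.2904
glycine,6.0920,5.0908,6.5590,5.7401
glycerophosphocholine,2.4215,2.6084,2.2208,2.1689
lactate,11.0040,2.4733,9.6770,2.1588
phosphorylcholine,1.1690,0.6396,0.9469,0.3644
taurine,2.9660,1.9594,2.7060,1.3103
threonine,1.1202,0.2821,1.1678,0.2801
glutamine,0.6855,0.2518,0.5633,0.1466
succinate,0.3069,0.2121,0.2595,0.1406
glucose,1.2247,0.6158,1.0736,0.7355
tyrosine,0.0520,0.0442,0.0552,0.0599
phenylalanine,0.1449,0.0771,0.1495,0.0880
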