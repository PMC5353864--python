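# Cohort design: pancreatic parenchyma (PP, n=9) vs pancreatic
# adenocarcinoma (PA, n=44), both without neoadjuvant chemotherapy.
# Concentrations in nmol/mg wet tissue, given as group mean and SD of a
# zero-truncated Gaussian.
# group PP: n=9 tissue=PP chemo=no survival=unknown
# group PA: n=44 tissue=PA chemo=no survival=unknown
metabolite,PP_mean,PP_sd,PA_mean,PA_sd
ascorbate,0.3488,0.2191,0.3988,0.2221
aspartate,0.7577,0.3284,0.6229,0.2255
choline,1.5580,0.5921,0.8849,0.3887
creatine,1.7371,0.9568,1.3561,0.5057
ethanolamine,0.9314,0.4502,0.6188,0.2620
glutamate,2.9830,0.8698,2.4650,0.7699
glycerol,8.1840,7.3988,2.2750,1.1994
glycine,6.0920,5.0908,2.2663,0.8577
glycerophosphocholine,2.4215,2.6084,1.0319,0.5029
lactate,11.0040,2.4733,16.1370,4.7272
phosphorylcholine,1.1696,0.6396,0.9764,0.5008
taurine,2.9660,1.9594,4.4630,1.4063
threonine,1.1202,0.2821,1.1931,0.4230
glutamine,0.6855,0.2518,0.6394,0.2272
succinate,0.3068,0.2121,0.1762,0.0763
glucose,1.2247,0.6158,1.3141,1.1020
tyrosine,0.0521,0.0443,0.0741,0.0472
phenylalanine,0.1449,0.0771,0.0741,0.0811
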