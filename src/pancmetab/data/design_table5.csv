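# Cohort design: long-term (>3 years, n=8) vs short-term (<1 year, n=9)
# survivors, all pancreatic adenocarcinoma without neoadjuvant chemotherapy.
# Concentrations in nmol/mg wet tissue.
# CAVEAT: the published group statistics for this comparison duplicate the
# no-chemo/chemo columns of the adenocarcinoma chemotherapy table row for
# row (means and SDs), which is internally suspicious; they are packaged
# as printed, without correction.
# group LongSurv: n=8 tissue=PA chemo=no survival=long
# group ShortSurv: n=9 tissue=PA chemo=no survival=short
metabolite,LongSurv_mean,LongSurv_sd,ShortSurv_mean,ShortSurv_sd
ascorbate,0.3988,0.2221,0.4062,0.2227
aspartate,0.6229,0.2255,0.9658,0.6074
choline,0.8849,0.3887,0.9539,0.4702
creatine,1.3561,0.5057,1.4464,0.5971
ethanolamine,0.6148,0.2620,0.7511,0.4177
glutamate,2.4650,0.7699,2.8070,0.9767
glycerol,2.7550,1.1994,3.5300,2.6914
glycine,2.2663,0.8577,2.9025,1.8798
glycerophosphocholine,1.0319,0.5029,1.0810,0.7982
lactate,16.1370,4.7272,15.9030,5.3324
phosphorylcholine,0.9764,0.5008,0.9518,0.4822
taurine,4.4630,1.4062,4.3490,1.3425
threonine,1.1931,0.4229,1.2957,0.6961
glutamine,0.6394,0.2272,0.6870,0.2668
succinate,0.1762,0.0763,0.1866,0.0739
glucose,1.3141,1.1020,2.3227,2.7375
tyrosine,0.0730,0.0493,0.1097,0.1479
phenylalanine,0.1789,0.0811,0.1097,0.1958
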