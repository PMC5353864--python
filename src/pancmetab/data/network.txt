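# Metabolic network over the 18 quantified metabolites.
# Edges are a minimal literature-style pathway adjacency (glycolysis, TCA via
# oxaloacetate contraction, phospholipid head-group chain, amino-acid
# transamination); they are packaged as plain text so users can substitute
# their own adjacency.  The [groups] section lists the pathway-related
# metabolite groups scored jointly by the mutual-information analysis, in
# their canonical order.
[nodes]
ascorbate
aspartate
choline
creatine
ethanolamine
glucose
glutamate
glutamine
glycerol
glycerophosphocholine
glycine
lactate
phenylalanine
phosphorylcholine
succinate
taurine
threonine
tyrosine
[edges]
glucose -- lactate
glucose -- glycerol
glucose -- glycine
glucose -- ascorbate
glycine -- glutamate
glycine -- creatine
glycine -- threonine
threonine -- aspartate
aspartate -- succinate
aspartate -- taurine
aspartate -- glutamate
glutamate -- glutamine
glutamate -- tyrosine
tyrosine -- phenylalanine
choline -- phosphorylcholine
phosphorylcholine -- glycerophosphocholine
glycerophosphocholine -- ethanolamine
choline -- glycine
[groups]
choline, phosphorylcholine, glycerophosphocholine, ethanolamine
glycerol, glucose
glucose, lactate
aspartate, threonine
glucose, glycine
aspartate, taurine
aspartate, succinate
glucose, ascorbate, glycine, glutamate
glutamate, glutamine
glutamate, glutamine, glycine
glutamate, glycine, creatine
tyrosine, phenylalanine
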