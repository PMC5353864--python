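# 1H/13C resonance assignments for metabolites identified in intact pancreatic
# tissue by 1D CPMG HRMAS NMR at 500.13 MHz.  quantify=1 marks the designated
# quantification peak(s): well-defined resonances without overlap in the 1D
# spectra.  Glucose is the only quantified metabolite with two designated
# peaks (the alpha and beta anomeric C1H), merged under canonical "glucose"
# and summed at quantification time.  Proton counts follow standard chemical
# structure (they are needed to correct peak integrals to molar amounts).
metabolite,canonical,group_label,shift_1h,shift_13c,n_protons,quantify
Leucine,leucine,delta-CH3,0.95,23.43,3,0
Leucine,leucine,delta'-CH3,0.95,24.75,3,0
Lactate,lactate,CH3,1.33,22.69,3,0
Lactate,lactate,CH,4.13,71.22,1,1
Glycine,glycine,CH2,3.56,44.05,2,1
Glycerol,glycerol,CH2-OH (d 2X),3.55,65.03,2,0
Glycerol,glycerol,CH2-OH (u 2X),3.64,65.07,2,1
Glycerol,glycerol,CH-OH,3.77,74.69,1,0
Glutamine,glutamine,alpha-CH,3.77,57.23,1,0
Glutamine,glutamine,gamma-CH2,2.44,33.52,2,1
Serine,serine,gamma-CH2,3.97,62.90,2,0
Taurine,taurine,CH2-NH3+,3.27,50.01,2,0
Taurine,taurine,CH2-SO3-,3.43,37.93,2,1
Valine,valine,gamma'-CH3,1.04,20.44,3,0
Valine,valine,alpha-CH-NH2,3.60,63.05,1,0
Arginine,arginine,gamma-CH2,1.65,25.90,2,0
Arginine,arginine,beta-CH2,1.92,30.13,2,0
Arginine,arginine,delta-CH2,3.22,43.23,2,0
beta-Glucose,glucose,C6H (d),3.89,63.48,1,0
beta-Glucose,glucose,C1H,4.65,98.70,1,1
alpha-Glucose,glucose,CH2,3.83,62.08,2,0
alpha-Glucose,glucose,C1H,5.22,94.94,1,1
Lysine,lysine,delta-CH2,1.73,29.17,2,0
Lysine,lysine,beta-CH2,1.90,32.48,2,0
Lysine,lysine,gamma-CH2,1.91,30.25,2,0
Glutamic acid,glutamate,beta-CH2,2.08,29.67,2,0
Glutamic acid,glutamate,gamma-CH2,2.35,35.96,2,1
Alanine,alanine,beta-CH3,1.48,18.87,3,0
Myo-Inositol,myo-inositol,(CH)2 a,3.54,73.81,2,0
Myo-Inositol,myo-inositol,(CH)2 b,3.63,75.11,2,0
Myo-Inositol,myo-inositol,CH,4.05,74.79,1,0
Ornithine,ornithine,alpha-CH-NH2,3.77,57.05,1,0
Ornithine,ornithine,delta-CH2-NH2,3.05,41.83,2,0
Ornithine,ornithine,beta-CH2,1.93,30.28,2,0
Ornithine,ornithine,gamma-CH2,1.74,25.52,2,0
3-Hydroxybutyric acid,3-hydroxybutyrate,CH3,1.20,24.30,3,0
Creatine,creatine,CH2,3.93,56.23,2,1
Choline,choline,N+-(CH3)3,3.23,56.48,9,1
Fatty acids (a),fatty acids (a),(1)CH2,1.30,32.16,2,0
Fatty acids (b),fatty acids (b),CH2,2.80,28.50,2,0
Fatty acids (c),fatty acids (c),(1)CH2,2.26,36.60,2,0
Succinic acid,succinate,(CH2)2,2.39,34.00,4,1
Ascorbate,ascorbate,CH-O,4.52,80.87,1,1
Ethanolamine,ethanolamine,CH2-NH2,3.13,43.90,2,1
Phosphorylcholine,phosphorylcholine,CH2-O,4.11,63.60,2,1
Phosphorylcholine,phosphorylcholine,N+-(CH3)3,3.22,56.57,9,0
Threonine,threonine,beta-CH,4.25,68.50,1,1
Glycerophosphocholine,glycerophosphocholine,N+-(CH3)3,3.21,56.56,9,0
Glycerophosphocholine,glycerophosphocholine,beta-CH2,3.72,68.49,2,0
Glycerophosphocholine,glycerophosphocholine,alpha-CH2,4.33,62.16,2,1
Glycerophosphocholine,glycerophosphocholine,CH2OH,3.93,73.32,2,0
Glycerophosphocholine,glycerophosphocholine,CH2-HPO4 (d),3.89,69.22,1,0
Tyrosine,tyrosine,meta CH,6.88,118.44,2,1
Tyrosine,tyrosine,ortho CH,7.18,133.30,2,0
Tyrosine,tyrosine,beta-CH2 (d),3.02,39.40,1,0
Phenylalanine,phenylalanine,ortho CH,7.31,131.91,2,0
Phenylalanine,phenylalanine,para CH,7.36,132.28,1,1
Phenylalanine,phenylalanine,meta CH,7.42,131.59,2,0
Aspartic acid,aspartate,beta-CH2 (d),2.63,40.20,1,1
Aspartic acid,aspartate,beta-CH2 (u),2.81,40.82,1,0
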