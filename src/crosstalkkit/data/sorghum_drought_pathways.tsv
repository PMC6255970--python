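pathway	functional_class	ko	n_genes
Arganine and proline metabolism	Amino acid metabolism	ko00330	11
Ascorbate and aldarate metabolism	Amino acid metabolism	ko00053	6
Cysteine and methionine metabolism	Amino acid metabolism	ko00270	4
Glycine, serine and threonine metabolism	Amino acid metabolism	ko00260	9
Histidine metabolism	Amino acid metabolism	ko00340	6
Lysine degradation	Amino acid metabolism	ko00310	5
Phenylalanine metabolism	Amino acid metabolism	ko00360	3
Tryptophane metabolism	Amino acid metabolism	ko00380	5
Tyrosine metabolism	Amino acid metabolism	ko00350	10
Valine, leucine and isoleucine degradation	Amino acid metabolism	ko00280	5
Carbapenem biosynthesis	Biosynthesis of other secondary metabolites	ko00332	4
Phenylpropanoid biosynthesis	Biosynthesis of other secondary metabolites	ko00940	5
Amino sugar and nucleotide sugar metabolism	Carbohydrate metabolism	ko00520	4
Galactose metabolism	Carbohydrate metabolism	ko00052	5
Glycolysis/Gluconeogenesis	Carbohydrate metabolism	ko00010	17
Glyoxylate and decarboxylate metabolism	Carbohydrate metabolism	ko00630	4
Pentose and glucuronate interconversion	Carbohydrate metabolism	ko00040	6
Pentose phosphate pathway	Carbohydrate metabolism	ko00030	5
Pyruvate metabolism	Carbohydrate metabolism	ko00620	8
Starch and sucrose metabolism	Carbohydrate metabolism	ko00500	10
Methane metabolism	Carbon metabolism	ko01200	4
Carbon fixation in photosynthetic organisms	Energy metabolism	ko00710	9
Oxidative phosphorylation	Energy metabolism	ko00190	7
mTOR signaling pathway	Environmental Information Processing; Signal transduction	ko04150	4
Alpha-Linolenic acid metabolism	Lipid metabolism	ko00592	7
Fatty acid degradation	Lipid metabolism	ko00071	11
Pantotenate and CoA biosynthesis	Metabolism of cofactors and vitamins	ko00770	3
Retinol metabolism	Metabolism of cofactors and vitamins	ko00830	6
Beta-alanine metabolism	Metabolism of other amino acids	ko00410	4
Glutathione metabolism	Metabolism of other amino acids	ko00480	10
Glycerolipid metabolism	Metabolism of other amino acids	ko00561	6
Biosynthesis of antibiotics	Metabolism of terpenoids and polyketides	ko01130	28
Carotenoid biosynthesis	Metabolism of terpenoids and polyketides	ko00906	5
Limonene and pinene degradation	Metabolism of terpenoids and polyketides	ko00903	5
Purine metabolism	Nucleotide metabolism	ko00230	6
Pyrimidine metabolism	Nucleotide metabolism	ko00240	3
Chloroalkane and chloroalkene degradation	Xenobiotics biodegradation and metabolism	ko00625	11
Drug metabolism—other enzymes	Xenobiotics biodegradation and metabolism	ko00983	4
Drug metabolism Cytochrome p450	Xenobiotics biodegradation and metabolism	ko00982	15
Metabolism of xenobiotics by cytochrome p450	Xenobiotics biodegradation and metabolism	ko00980	12
Naphtalene degradation	Xenobiotics biodegradation and metabolism	ko00626	5
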