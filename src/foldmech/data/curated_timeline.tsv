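cath_id	nd	description	step_type
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Bimolecular nucleophilic addition
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Bimolecular nucleophilic substitution
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Intramolecular nucleophilic addition
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Proton transfer
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Unimolecular elimination by the conjugate base
3.40.50.300	0.0000	P-loop containing nucleotide triphosphate hydrolases	Electron transfer
3.40.50.150	0.0098	Vaccinia Virus protein VP39	Bimolecular elimination
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Bimolecular elimination
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Aromatic bimolecular nucleophilic addition
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Aromatic unimolecular elimination by the conjugate base
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Assisted keto-enol tautomerisation
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Aromatic intramolecular elimination
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Bimolecular homolytic addition
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Radical formation
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Radical termination
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Redox
3.40.50.720	0.0098	NAD(P)-binding Rossmann-like Domain	Bimolecular electrophilic addition
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Bimolecular elimination
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Aromatic bimolecular nucleophilic addition
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Aromatic unimolecular elimination by the conjugate base
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Assisted keto-enol tautomerisation
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Aromatic intramolecular elimination
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Bimolecular homolytic addition
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Radical formation
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Radical termination
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Colligation
3.50.50.60	0.0098	FAD/NAD(P)-binding domain	Redox
3.40.50.620	0.0147	HUPs	Intramolecular elimination
3.20.20.70	0.0196	Aldolase class I	Unimolecular elimination by the conjugate base
3.20.20.70	0.0196	Aldolase class I	Redox
3.20.20.70	0.0196	Aldolase class I	Radical termination
3.20.20.70	0.0196	Aldolase class I	Radical formation
3.20.20.70	0.0196	Aldolase class I	Proton transfer
3.20.20.70	0.0196	Aldolase class I	Other tautomerisation
3.20.20.70	0.0196	Aldolase class I	Intramolecular nucleophilic addition
3.20.20.70	0.0196	Aldolase class I	Intramolecular elimination
3.20.20.70	0.0196	Aldolase class I	Hydride transfer
3.20.20.70	0.0196	Aldolase class I	Heterolysis
3.20.20.70	0.0196	Aldolase class I	Electron transfer
3.20.20.70	0.0196	Aldolase class I	Bimolecular nucleophilic substitution
3.20.20.70	0.0196	Aldolase class I	Bimolecular nucleophilic addition
3.20.20.70	0.0196	Aldolase class I	Bimolecular elimination
3.20.20.70	0.0196	Aldolase class I	Assisted other tautomerisation
3.20.20.70	0.0196	Aldolase class I	Assisted keto-enol tautomerisation
3.20.20.70	0.0196	Aldolase class I	Aromatic unimolecular elimination by the conjugate base
3.20.20.70	0.0196	Aldolase class I	Aromatic bimolecular nucleophilic addition
3.20.20.70	0.0196	Aldolase class I	Aromatic bimolecular elimination
3.20.20.70	0.0196	Aldolase class I	Aldol addition
3.40.50.970	0.0490	1-deoxy-D-xylulose-5-phosphate synthase-like domain	Homolysis
3.40.50.970	0.0490	1-deoxy-D-xylulose-5-phosphate synthase-like domain	Elimination reaction
3.40.190.10	0.0490	Periplasmic binding protein-like II	Aromatic bimolecular nucleophilic substitution
3.90.226.10	0.0539	2-enoyl-CoA Hydratase, chain A domain 1	Keto-Enol tautomerisation
3.90.226.10	0.0539	2-enoyl-CoA Hydratase, chain A domain 1	Intramolecular electrophilic addition
3.40.47.10	0.0588	Peroxisomal Thiolase, chain A domain 1	Claisen condensation
3.40.30.10	0.0588	Glutaredoxin	Intramolecular nucleophilic substitution
3.60.21.10	0.0686	Purple Acid Phosphatase, chain A domain 2	Coordination
2.60.120.10	0.0784	Jelly Rolls	Radical propagation
3.40.50.1820	0.0784	Carboxyesterase-related protein-like domain 1	Substitution reaction
3.20.70.20	0.1471	Anaerobic ribonucleotide-triphosphate reductase large chain	Bimolecular homolytic substitution
3.20.70.20	0.1471	Anaerobic ribonucleotide-triphosphate reductase large chain	Hydrogen transfer
3.20.70.20	0.1471	Anaerobic ribonucleotide-triphosphate reductase large chain	Unimolecular homolytic elimination
1.10.600.10	0.1765	Farnesyl Diphosphate Synthase	Intramolecular electrophilic substitution
1.10.600.10	0.1765	Farnesyl Diphosphate Synthase	Intramolecular rearrangement
2.40.100.10	0.2059	Cyclophilin	Isomerisation
3.40.50.10090	0.2549	Uroporphyrinogen-III synthase-like domain	Aromatic intramolecular electrophilic substitution
3.30.1130.10	0.2745	GTP Cyclohydrolase I, domain 2	Amadori rearrangement
1.10.520.10	0.4412	Catalase-peroxidase-like domain	Bond order change
3.40.50.10230	0.4902	Precorrin-8X methylmutase CbiC/CobH	Sigmatropic rearrangement
3.40.50.10230	0.4902	Precorrin-8X methylmutase CbiC/CobH	Pericyclic reaction
1.10.606.10	0.5686	Vanadium-containing Chloroperoxidase domain 2	Acidic bimolecular nucleophilic substitution
1.10.590.10	0.5980	Chorismate Mutase subunit A	Claisen rearrangement
3.20.20.240	0.6373	TIM Barrel	Intramolecular homolytic addition
3.20.20.240	0.6373	TIM Barrel	Bimolecular homolytic elimination
1.25.40.80	0.6422	Serine Threonine Protein Phosphatase 5, Tetratricopeptide repeat	Photochemical activation
1.10.800.10	0.7304	Phenylalanine Hydroxylase	Aromatic bimolecular electrophilic addition
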