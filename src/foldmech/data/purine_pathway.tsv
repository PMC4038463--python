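macie_id	name	ec_number	cath_id	nd	step_type
M0290	adenylate kinase	2.7.4.3	3.40.50.300	0.0000	Bimolecular nucleophilic substitution
M0234	GMP synthase (glutamine-hydrolysing)	6.3.5.2	3.40.50.880	0.0980	Proton transfer
M0234	GMP synthase (glutamine-hydrolysing)	6.3.5.2	3.40.50.880	0.0980	Bimolecular nucleophilic substitution
M0234	GMP synthase (glutamine-hydrolysing)	6.3.5.2	3.40.50.880	0.0980	Unimolecular elimination by the conjugate base
M0234	GMP synthase (glutamine-hydrolysing)	6.3.5.2	3.40.50.880	0.0980	Bimolecular nucleophilic addition
M0326	pyruvate kinase	2.7.1.40	3.20.20.60	0.1127	Proton transfer
M0326	pyruvate kinase	2.7.1.40	3.20.20.60	0.1127	Bimolecular nucleophilic substitution
M0326	pyruvate kinase	2.7.1.40	2.40.33.10	0.4118	Proton transfer
M0326	pyruvate kinase	2.7.1.40	2.40.33.10	0.4118	Bimolecular nucleophilic substitution
M0080	adenylosuccinate lyase	4.3.2.2	1.20.200.10	0.1667	Proton transfer
M0080	adenylosuccinate lyase	4.3.2.2	1.20.200.10	0.1667	Bimolecular elimination
M0065	adenylosuccinate synthase	6.3.4.4	3.40.440.10	0.2353	Proton transfer
M0065	adenylosuccinate synthase	6.3.4.4	3.40.440.10	0.2353	Bimolecular nucleophilic substitution
M0065	adenylosuccinate synthase	6.3.4.4	3.40.440.10	0.2353	Assisted other tautomerisation
M0065	adenylosuccinate synthase	6.3.4.4	3.40.440.10	0.2353	Aromatic bimolecular nucleophilic substitution
M0150	nucleoside-diphosphate kinase	2.7.4.6	3.30.70.141	0.3186	Proton transfer
M0150	nucleoside-diphosphate kinase	2.7.4.6	3.30.70.141	0.3186	Bimolecular nucleophilic substitution
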