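# Mechanistic step-type vocabulary (51 MACiE annotation names, one per line,
# alphabetical). Matched case-sensitively.
Acidic bimolecular nucleophilic substitution
Aldol addition
Amadori rearrangement
Aromatic bimolecular electrophilic addition
Aromatic bimolecular elimination
Aromatic bimolecular nucleophilic addition
Aromatic bimolecular nucleophilic substitution
Aromatic intramolecular electrophilic substitution
Aromatic intramolecular elimination
Aromatic unimolecular elimination by the conjugate base
Assisted keto-enol tautomerisation
Assisted other tautomerisation
Bimolecular electrophilic addition
Bimolecular elimination
Bimolecular homolytic addition
Bimolecular homolytic elimination
Bimolecular homolytic substitution
Bimolecular nucleophilic addition
Bimolecular nucleophilic substitution
Bond order change
Claisen condensation
Claisen rearrangement
Colligation
Coordination
Electron transfer
Elimination reaction
Heterolysis
Homolysis
Hydride transfer
Hydrogen transfer
Intramolecular electrophilic addition
Intramolecular electrophilic substitution
Intramolecular elimination
Intramolecular homolytic addition
Intramolecular nucleophilic addition
Intramolecular nucleophilic substitution
Intramolecular rearrangement
Isomerisation
Keto-Enol tautomerisation
Other tautomerisation
Pericyclic reaction
Photochemical activation
Proton transfer
Radical formation
Radical propagation
Radical termination
Redox
Sigmatropic rearrangement
Substitution reaction
Unimolecular elimination by the conjugate base
Unimolecular homolytic elimination
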