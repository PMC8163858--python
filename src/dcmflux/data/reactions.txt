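# Acetogenic (Wood-Ljungdahl) core of dichloromethane fermentation.
# Grammar: name: [coeff] species + ... -> [coeff] species + ...
# The tetrahydrofolate carrier is the pseudo-element Fol, so it cancels in balances.
dcm_to_methylene: 4 CH2Cl2 + 4 FH4 -> 4 CH2=FH2 + 8 H+ + 8 Cl-
methylene_oxidation: 3 CH2=FH2 + 9 H2O -> 3 HCO3- + 12 e- + 3 FH4 + 15 H+
methylene_to_acetate: CH2=FH2 + 4 e- + HCO3- + 4 H+ -> CH3COO- + H2O + FH4
bicarbonate_to_acetate: 2 HCO3- + 9 H+ + 8 e- -> CH3COO- + 4 H2O
dcm_fermentation_net: 2 CH2Cl2 + 2 H2O -> CH3COO- + 5 H+ + 4 Cl-
# Quaternary-amine demethylation / reductive cleavage chain.
choline_oxidation: choline + H2O -> glycine-betaine + 5 H+ + 4 e-
betaine_demethylation: glycine-betaine + FH4 -> dimethylglycine + CH3-FH4
dimethylglycine_demethylation: dimethylglycine + FH4 -> sarcosine + CH3-FH4
sarcosine_reductive_cleavage: sarcosine + H+ + 2 e- -> CH3COO- + monomethylamine
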