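name	formula	charge
CH2Cl2	CH2Cl2	0
H2O	H2O	0
H+	H	1
Cl-	Cl	-1
e-	-	-1
HCO3-	CHO3	-1
CO2	CO2	0
CH3COO-	C2H3O2	-1
FH4	Fol	0
CH2=FH2	FolC	0
CH3-FH4	FolCH2	0
choline	C5H14NO	1
glycine-betaine	C5H11NO2	0
dimethylglycine	C4H9NO2	0
sarcosine	C3H7NO2	0
monomethylamine	CH5N	0
methanol	CH4O	0
H2	H2	0
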