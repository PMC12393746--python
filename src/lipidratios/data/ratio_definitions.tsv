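label	numerator	denominator	annotation	provenance
Total PE Ether/PE	Total PE Ether	PE	ether vs diacyl	printed
Total PC Ether/PC	Total PC Ether	PC	ether vs diacyl	printed
PE(P)/PE	PE(P)	PE	ether vs diacyl	printed
PE(O)/PE	PE(O)	PE	ether vs diacyl	printed
PC(P)/PC	PC(P)	PC	ether vs diacyl	printed
PC(O)/PC	PC(O)	PC	ether vs diacyl	printed
TG(O)/TG	TG(O)	TG	ether vs diacyl	printed
PE(O)/PE(P)	PE(O)	PE(P)	PEDS1	printed
PC(P)/PE(P)	PC(P)	PE(P)	PEMT/C-PT	printed
LPE(P)/PE(P)	LPE(P)	PE(P)	iPLA2/LPAT	printed
LPC(P)/PC(P)	LPC(P)	PC(P)	iPLA2/LPAT	printed
LPE/PE	LPE	PE	PLA2	printed
LPC/PC	LPC	PC	PLA2/LCAT	printed
PE/PC	PE	PC	PEMT	printed
PC(O)/PC(P)	PC(O)	PC(P)	PEDS1	printed
LPC(O)/PC(O)	LPC(O)	PC(O)	PLA2	printed
LPE(P)/LPE	LPE(P)	LPE	ether vs diacyl	printed
PE(P-16:0/18:3) [n-3]/PE(P-16:0/20:5)	PE(P-16:0/18:3) [n-3]	PE(P-16:0/20:5)	omega-3	printed
PE(P-18:0/18:3) [n-3]/PE(P-18:0/20:5)	PE(P-18:0/18:3) [n-3]	PE(P-18:0/20:5)	omega-3	printed
PE(P-16:0/20:5)/PE(P-16:0/22:5) [n-3]	PE(P-16:0/20:5)	PE(P-16:0/22:5) [n-3]	omega-3	printed
PE(P-18:0/20:5)/PE(P-18:0/22:5) [n-3]	PE(P-18:0/20:5)	PE(P-18:0/22:5) [n-3]	omega-3	printed
PE(P-16:0/22:5) [n-3]/PE(P-16:0/22:6)	PE(P-16:0/22:5) [n-3]	PE(P-16:0/22:6)	omega-3	printed
PE(P-18:0/22:5) [n-3]/PE(P-18:0/22:6)	PE(P-18:0/22:5) [n-3]	PE(P-18:0/22:6)	omega-3	printed
PE(P-16:0/18:2)/PE(P-16:0/20:4)	PE(P-16:0/18:2)	PE(P-16:0/20:4)	omega-6	printed
PE(P-18:0/18:2)/PE(P-18:0/20:4)	PE(P-18:0/18:2)	PE(P-18:0/20:4)	omega-6	printed
PE(P-16:0/20:4)/PE(P-16:0/22:4)	PE(P-16:0/20:4)	PE(P-16:0/22:4)	omega-6	printed
PE(P-18:0/20:4)/PE(P-18:0/22:4)	PE(P-18:0/20:4)	PE(P-18:0/22:4)	omega-6	printed
PE(P-16:0/22:4)/PE(P-16:0/22:5) [n-6]	PE(P-16:0/22:4)	PE(P-16:0/22:5) [n-6]	omega-6	printed
PE(P-18:0/22:4)/PE(P-18:0/22:5) [n-6]	PE(P-18:0/22:4)	PE(P-18:0/22:5) [n-6]	omega-6	printed
PE(P-16:0/18:2)/PE(P-18:0/18:2)	PE(P-16:0/18:2)	PE(P-18:0/18:2)	DNL sn-1	printed
PE(P-16:0/20:4)/PE(P-18:0/20:4)	PE(P-16:0/20:4)	PE(P-18:0/20:4)	DNL sn-1	printed
PE(P-16:0/22:4)/PE(P-18:0/22:4)	PE(P-16:0/22:4)	PE(P-18:0/22:4)	DNL sn-1	printed
PE(P-16:0/22:6)/PE(P-18:0/22:6)	PE(P-16:0/22:6)	PE(P-18:0/22:6)	DNL sn-1	printed
PC(P-16:0/20:4)/PE(P-16:0/20:4)	PC(P-16:0/20:4)	PE(P-16:0/20:4)	PEMT/C-PT	printed
PE(P-16:0/18:3) [n-3]/PE(P-18:0/18:3) [n-3]	PE(P-16:0/18:3) [n-3]	PE(P-18:0/18:3) [n-3]	DNL sn-1	printed
PE(P-16:0/18:3) [n-3]/PE(P-18:1/18:3)	PE(P-16:0/18:3) [n-3]	PE(P-18:1/18:3)	sn-1 composition	printed
PE(16:0_18:2)/PE(16:0_20:4)	PE(16:0_18:2)	PE(16:0_20:4)	omega-6	printed
LPC(20:4) [sn2]/LPC(22:4) [sn2]	LPC(20:4) [sn2]	LPC(22:4) [sn2]	omega-6	printed
LPC(22:5) [sn2]/LPC(22:6) [sn2]	LPC(22:5) [sn2]	LPC(22:6) [sn2]	omega-3	printed
LPE(16:0) [sn1]/LPE(18:0) [sn1]	LPE(16:0) [sn1]	LPE(18:0) [sn1]	DNL	printed
LPE(16:0) [sn1]/LPE(18:1) [sn1]	LPE(16:0) [sn1]	LPE(18:1) [sn1]	DNL	printed
LPC(16:0) [sn1]/LPC(18:0) [sn1]	LPC(16:0) [sn1]	LPC(18:0) [sn1]	DNL	printed
LPC(16:0) [sn1]/LPC(18:1) [sn1]	LPC(16:0) [sn1]	LPC(18:1) [sn1]	DNL	printed
LPE(16:0) [sn2]/LPE(18:0) [sn2]	LPE(16:0) [sn2]	LPE(18:0) [sn2]	DNL	printed
LPE(16:0) [sn2]/LPE(18:2) [sn2]	LPE(16:0) [sn2]	LPE(18:2) [sn2]	DNL	printed
LPC(16:0) [sn2]/LPC(18:0) [sn2]	LPC(16:0) [sn2]	LPC(18:0) [sn2]	DNL	printed
LPC(16:0) [sn2]/LPC(18:2) [sn2]	LPC(16:0) [sn2]	LPC(18:2) [sn2]	DNL	printed
PE(18:0_22:4)/PE(18:0_22:5)	PE(18:0_22:4)	PE(18:0_22:5)	omega-6	printed
PE(18:0_22:5)/PE(18:0_22:6)	PE(18:0_22:5)	PE(18:0_22:6)	omega-3	printed
PC(18:0_22:4)/PC(18:0_22:5)	PC(18:0_22:4)	PC(18:0_22:5)	omega-6	printed
PE(18:0_18:2)/PE(18:0_20:4)	PE(18:0_18:2)	PE(18:0_20:4)	omega-6	reconstructed
PC(16:0_18:2)/PC(16:0_20:4)	PC(16:0_18:2)	PC(16:0_20:4)	omega-6	reconstructed
PC(18:0_18:2)/PC(18:0_20:4)	PC(18:0_18:2)	PC(18:0_20:4)	omega-6	reconstructed
PE(O-16:0/20:4)/PE(P-16:0/20:4)	PE(O-16:0/20:4)	PE(P-16:0/20:4)	PEDS1	reconstructed
PE(O-18:0/20:4)/PE(P-18:0/20:4)	PE(O-18:0/20:4)	PE(P-18:0/20:4)	PEDS1	reconstructed
PE(O-16:0/22:6)/PE(P-16:0/22:6)	PE(O-16:0/22:6)	PE(P-16:0/22:6)	PEDS1	reconstructed
PC(O-16:0/20:4)/PC(P-16:0/20:4)	PC(O-16:0/20:4)	PC(P-16:0/20:4)	PEDS1	reconstructed
PC(O-18:0/20:4)/PC(P-18:0/20:4)	PC(O-18:0/20:4)	PC(P-18:0/20:4)	PEDS1	reconstructed
PC(O-16:0/22:6)/PC(P-16:0/22:6)	PC(O-16:0/22:6)	PC(P-16:0/22:6)	PEDS1	reconstructed
PC(16:0_18:1)/PC(18:0_18:1)	PC(16:0_18:1)	PC(18:0_18:1)	DNL	reconstructed
LPE(P-16:0)/LPE(P-18:0)	LPE(P-16:0)	LPE(P-18:0)	DNL sn-1	reconstructed
LPC(P-16:0)/LPC(P-18:0)	LPC(P-16:0)	LPC(P-18:0)	DNL sn-1	reconstructed
LPC(O-16:0)/LPC(O-18:0)	LPC(O-16:0)	LPC(O-18:0)	DNL sn-1	reconstructed
LPE(P)/PE	LPE(P)	PE	ether vs diacyl	reconstructed
LPC(P)/PC	LPC(P)	PC	ether vs diacyl	reconstructed
LPC(O)/PC	LPC(O)	PC	ether vs diacyl	reconstructed
DG/TG	DG	TG	DGAT	reconstructed
TG(O)/DG	TG(O)	DG	ether neutral	reconstructed
SM/Cer	SM	Cer	sphingomyelinase	reconstructed
Cer/Sph	Cer	Sph	ceramidase	reconstructed
HexCer/Cer	HexCer	Cer	GlcCer synthase	reconstructed
Hex2Cer/HexCer	Hex2Cer	HexCer	glycosylation	reconstructed
Hex3Cer/Hex2Cer	Hex3Cer	Hex2Cer	glycosylation	reconstructed
GM3/Hex2Cer	GM3	Hex2Cer	ganglioside synthesis	reconstructed
dhCer/Cer	dhCer	Cer	DES1	reconstructed
dhSM/SM	dhSM	SM	DES1	reconstructed
CE/COH	CE	COH	LCAT	reconstructed
LPI/PI	LPI	PI	PLA2	reconstructed
LPS/PS	LPS	PS	PLA2	reconstructed
LPG/PG	LPG	PG	PLA2	reconstructed
LPA/PA	LPA	PA	PLA2	reconstructed
DG/PA	DG	PA	lipin	reconstructed
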