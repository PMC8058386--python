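gene	sign	branch	citations
ATR	+	Strand invasion (SI)	B31,B32,B24,B26
ATRX	-	G4 formation; DDR provocation	B48,B19,B28
BLM	+	Holliday junction dissolution	B70
CHEK1	+	Strand invasion (SI)	B26
DAXX	-	G4 formation; DDR provocation	B48,B19,B28
ERCC1	-	Holliday junction resolution	B80
ERCC4	-	Holliday junction resolution	B80
H3F3A	-	G4 formation; DDR provocation	B48,B19,B28
HNRNPA1	-	Strand invasion (SI)	B31
MND1	+	Strand invasion (SI)	B16,B41
MRE11	+	Holliday junction dissolution	B45
NBN	+	Holliday junction dissolution	B45
NR2C2	+	Telomere bridge formation (NTB)	B21
NR2F2	+	Telomere bridge formation (NTB)	B21
NSMCE2	+	Recruitment of telomeres to APBs (APB)	B62,B3
PCNA	+	Template directed synthesis	B26
PML	+	Recruitment of telomeres to APBs (APB)	B18
POLD3	+	Template directed synthesis	B26
POT1	-	Strand invasion (SI)	B31
PSMC3IP	+	Strand invasion (SI)	B16,B41
RAD50	+	Holliday junction dissolution	B45
RAD51	+	Strand invasion (SI)	B16,B41
RAD52	+	Strand invasion (SI)	B41,B51
RFC1	+	Template directed synthesis	B26
RMI1	+	Holliday junction dissolution	B70
RMI2	+	Holliday junction dissolution	B70
RPA1	+	Strand invasion (SI)	B31
RPA2	+	Strand invasion (SI)	B31
RPA3	+	Strand invasion (SI)	B31
SLX1A	-	Holliday junction resolution	B70
SLX1B	-	Holliday junction resolution	B70
SLX4	-	Holliday junction resolution	B70
SMC5	+	Recruitment of telomeres to APBs (APB)	B62,B3
SMC6	+	Recruitment of telomeres to APBs (APB)	B62,B3
SP100	-	Holliday junction dissolution	B42
TOP3A	+	Holliday junction dissolution	B70
ZNF827	+	Telomere bridge formation (NTB)	B21
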