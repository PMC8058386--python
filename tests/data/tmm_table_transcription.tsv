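pathway	branch	gene	sign	complex
ALT	G4 formation; DDR provocation	H3F3A	-
ALT	G4 formation; DDR provocation	DAXX	-	ATRX/DAXX
ALT	G4 formation; DDR provocation	ATRX	-	ATRX/DAXX
ALT	Telomere bridge formation (NTB)	NR2C2	+
ALT	Telomere bridge formation (NTB)	NR2F2	+
ALT	Telomere bridge formation (NTB)	ZNF827	+
ALT	Recruitment of telomeres to APBs (APB)	PML	+
ALT	Recruitment of telomeres to APBs (APB)	SMC5	+	SMC5/6
ALT	Recruitment of telomeres to APBs (APB)	SMC6	+	SMC5/6
ALT	Recruitment of telomeres to APBs (APB)	NSMCE2	+	SMC5/6
ALT	Strand invasion (SI)	POT1	-
ALT	Strand invasion (SI)	RPA1	+	RPA
ALT	Strand invasion (SI)	RPA2	+	RPA
ALT	Strand invasion (SI)	RPA3	+	RPA
ALT	Strand invasion (SI)	HNRNPA1	-
ALT	Strand invasion (SI)	ATR	+
ALT	Strand invasion (SI)	CHEK1	+
ALT	Strand invasion (SI)	RAD51	+
ALT	Strand invasion (SI)	PSMC3IP	+
ALT	Strand invasion (SI)	MND1	+
ALT	Strand invasion (SI)	RAD52	+
ALT	Template directed synthesis	POLD3	+
ALT	Template directed synthesis	PCNA	+
ALT	Template directed synthesis	RFC1	+
ALT	Holliday junction dissolution	MRE11	+	MRN
ALT	Holliday junction dissolution	RAD50	+	MRN
ALT	Holliday junction dissolution	NBN	+	MRN
ALT	Holliday junction dissolution	SP100	-
ALT	Holliday junction dissolution	BLM	+	BTR
ALT	Holliday junction dissolution	TOP3A	+	BTR
ALT	Holliday junction dissolution	RMI1	+	BTR
ALT	Holliday junction dissolution	RMI2	+	BTR
ALT	Holliday junction resolution	SLX1A	-	SLX4-SLX1-ERCC4
ALT	Holliday junction resolution	SLX1B	-	SLX4-SLX1-ERCC4
ALT	Holliday junction resolution	SLX4	-	SLX4-SLX1-ERCC4
ALT	Holliday junction resolution	ERCC1	-	SLX4-SLX1-ERCC4
ALT	Holliday junction resolution	ERCC4	-	SLX4-SLX1-ERCC4
TEL	Nuclear TERT (TERT activation and recruitment)	TERT	+
TEL	Nuclear TERT (TERT activation and recruitment)	KPNA1	+
TEL	Nuclear TERT (TERT activation and recruitment)	RAN	+
TEL	Nuclear TERT (TERT activation and recruitment)	IPO7	+
TEL	Nuclear TERT (TERT activation and recruitment)	RANBP2	+
TEL	Nuclear TERT (TERT activation and recruitment)	HSP90AA1	+	HSP90
TEL	Nuclear TERT (TERT activation and recruitment)	HSP90AB1	+	HSP90
TEL	Nuclear TERT (TERT activation and recruitment)	PTGES3	+
TEL	Nuclear TERT (TERT activation and recruitment)	STUB1	-
TEL	hTR maturation	TERC	+
TEL	hTR maturation	PARN	+
TEL	hTR maturation	WRAP53	+
TEL	hTR maturation	TENT4B	-	TRAMP
TEL	hTR maturation	MTREX	-	TRAMP
TEL	hTR maturation	ZCCHC7	-	TRAMP
TEL	Dyskerin complex (DKC1 branch)	DKC1	+	DKC1-NOP10-NHP2-NAF1
TEL	Dyskerin complex (DKC1 branch)	NOP10	+	DKC1-NOP10-NHP2-NAF1
TEL	Dyskerin complex (DKC1 branch)	NHP2	+	DKC1-NOP10-NHP2-NAF1
TEL	Dyskerin complex (DKC1 branch)	NAF1	+	DKC1-NOP10-NHP2-NAF1
TEL	Dyskerin complex (DKC1 branch)	GAR1	+
TEL	Telomerase assembly	TERT	+
TEL	Telomerase assembly	TERC	+
TEL	Telomerase assembly	DKC1	+
TEL	Telomerase assembly	RUVBL1	+	Pontin/Reptin
TEL	Telomerase assembly	RUVBL2	+	Pontin/Reptin
TEL	Recruitment to telomeres and synthesis	CTC1	+	CST
TEL	Recruitment to telomeres and synthesis	STN1	+	CST
TEL	Recruitment to telomeres and synthesis	TEN1	+	CST
TEL	Recruitment to telomeres and synthesis	POLA1	+
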