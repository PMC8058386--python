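gene	sign	branch	citations
CTC1	+	Recruitment to telomeres and synthesis	B13
DKC1	+	Dyskerin complex (DKC1 branch)	B67
GAR1	+	Dyskerin complex (DKC1 branch)	B67
HSP90AA1	+	Nuclear TERT (TERT activation and recruitment)	B40
HSP90AB1	+	Nuclear TERT (TERT activation and recruitment)	B40
IPO7	+	Nuclear TERT (TERT activation and recruitment)	B33
KPNA1	+	Nuclear TERT (TERT activation and recruitment)	B40
MTREX	-	hTR maturation	B74
NAF1	+	Dyskerin complex (DKC1 branch)	B67
NHP2	+	Dyskerin complex (DKC1 branch)	B67
NOP10	+	Dyskerin complex (DKC1 branch)	B67
PARN	+	hTR maturation	B52,B7
POLA1	+	Recruitment to telomeres and synthesis	B13
PTGES3	+	Nuclear TERT (TERT activation and recruitment)	B40
RAN	+	Nuclear TERT (TERT activation and recruitment)	B40
RANBP2	+	Nuclear TERT (TERT activation and recruitment)	B33
RUVBL1	+	Telomerase assembly	B75
RUVBL2	+	Telomerase assembly	B75
STN1	+	Recruitment to telomeres and synthesis	B13
STUB1	-	Nuclear TERT (TERT activation and recruitment)	B46
TEN1	+	Recruitment to telomeres and synthesis	B13
TENT4B	-	hTR maturation	B52,B74
TERC	+	hTR maturation	B11,B20
TERT	+	Nuclear TERT (TERT activation and recruitment)	B20
WRAP53	+	hTR maturation	B14
ZCCHC7	-	hTR maturation	B74
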