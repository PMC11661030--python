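abbreviation	name	class	cas	salmonella	in_vivo_liver	liver_carcinogen	iarc_group
AAF	2-acetylaminofluorene	GTHC	53-96-3	+	MN+, UDS+	+	NL
AFL	aflatoxin B1	GTHC	1402-68-2	+	UDS+	+	1
2NF	2-nitrofluorene	GTHC	607-57-8	+	UDS+	+	2B
DEN	N-nitrosodiethylamine	GTHC	55-18-5	+	UDS+, DNA single strand scission+	+	2A
NNM	N-nitrosomorpholine	GTHC	59-89-2	+	UDS+	+	2B
CLO	clofibrate	NGTHC	637-07-0	-	Pig-a-, UDS-, DSB-, MN+	+	3
ETH	ethanol	NGTHC	64-17-5	-	comet-, DNA strand break+	+	1
FEN	fenofibrate	NGTHC	49562-28-9	-	comet+ (weak), ND (UDS, MN)	+	NL
GEM	gemfibrozil	NGTHC	25812-30-0	-	ND	+	3
HEX	hexachlorobenzene	NGTHC	118-74-1	-	dominant lethal test-	+	2B
PHE	phenobarbital	NGTHC	50-06-6	-	MN-, comet-, Pig-a-	+	2B
WY	WY-14643	NGTHC	50892-23-4	-	UDS-	+	NL
AA	allyl alcohol	NGTNHC	107-18-6	-	ND	-	NL
ASP	aspirin	NGTNHC	50-78-2	-	ND	-	NL
CAF	caffeine	NGTNHC	58-08-2	-	ND	-	3
CPA	chlorpheniramine	NGTNHC	113-92-8	-	ND	-	NL
CPP	chlorpropamide	NGTNHC	94-20-2	-	ND	-	NL
DEX	dexamethasone	NGTNHC	50-02-2	-	ND	-	NL
DIA	diazepam	NGTNHC	439-14-5	-	ND	-	3
IND	indomethacin	NGTNHC	53-86-1	-	ND	-	NL
PBZ	phenylbutazone	NGTNHC	50-33-9	-	ND	-	3
THE	theophylline	NGTNHC	58-55-9	-	ND	-	3
TOL	tolbutamide	NGTNHC	64-77-7	-	ND	-	NL
MP	methapyrilene	INTERMEDIATE	91-80-5	-	MN+, comet-, UDS-	+	NL
MCT	monocrotaline	INTERMEDIATE	315-22-0	-	MN+, DNA-DNA interstrand crosslinks+	+	2B
TAA	thioacetamide	INTERMEDIATE	62-55-5	-	comet+, gamma-H2AX+, MN-	+	2B
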