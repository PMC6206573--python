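drug_id	drug	disease	targets
DB00065	Infliximab	colitis	TNF
DB00244	Mesalazine	colitis	PTGS2,PTGS1,ALOX5,PPARG,MPO
DB00795	Sulfasalazine	colitis	ALOX5,PTGS2,PTGS1,PPARG,PLA2G1B
DB01014	Balsalazide	colitis	PPARG,PTGS2,PTGS1,ALOX5
DB01250	Olsalazine	colitis	IFNG
DB06674	Golimumab	colitis	TNF
DB00030	Insulin Human	DM	INSR,RB1
DB00046	Insulin Lispro	DM	INSR
DB00047	Insulin Glargine	DM	INSR
DB00071	Insulin Pork	DM	INSR,RB1
DB00284	Acarbose	DM	MGAM
DB00412	Rosiglitazone	DM	PPARG
DB00491	Miglitol	DM	MGAM
DB00731	Nateglinide	DM	PPARG
DB00912	Repaglinide	DM	PPARG
DB01016	Glyburide	DM	ABCA1
DB01067	Glipizide	DM	PPARG
DB01120	Gliclazide	DM	VEGFA
DB01132	Pioglitazone	DM	PPARG
DB01252	Mitiglinide	DM	PPARG
DB01306	Insulin Aspart	DM	INSR
DB01307	Insulin Detemir	DM	INSR
DB01309	Insulin Glulisine	DM	INSR
DB04878	Voglibose	DM	MGAM
DB00997	Doxorubicin	GC	TOP2A
DB05448	PX-12	GC	EGFR
DB05457	OSI-7904L	GC	BCL2
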