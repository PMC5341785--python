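patient_id	population	gene	aa_change	af_validation_pct	af_discovery_pct	cadd_scaled	in_databases
MS-12	CD8+	CD1C	R89C	4.63	4.71	10.0	False
MS-8	CD19+	TRAF2	409-410 LF/L	4.03	2.71	21.6	False
MS-19	CD8+	CD46	A250T	2.88	2.29	23.4	False
MS-21	CD8+	RBM6	P24S	2.81	2.70	25.3	False
MS-2	CD8+	A2ML1	R1001W	2.71	2.70	32.0	True
MS-1	CD8+	IKZF3	155-156 FT/S	2.28	1.62	22.9	False
MS-2	CD8+	BTK	Splicing	2.23	2.14	24.2	False
MS-19	CD8+	PTPMT1	I165V	1.58	1.69	17.0	False
MG-5	others	CD56/NCAM1	G417R	1.58	1.29	34.0	False
MS-19	CD8+	ITGA2	Q581K	1.36	0.70	16.4	True
MS-21	CD8+	CD56/NCAM1	R358X	1.22	0.86	18.2	False
MS-8	CD8+	RPA1	L394P	1.21	1.68	25.5	False
MS-8	CD8+	KIR3DL2	D392Y	0.98	1.32	23.4	False
MS-21	CD8+	RORA	R533Q	0.95	1.15	23.0	False
MS-19	CD8+	PSG1	S23T	0.83	1.23	12.4	True
MS-3	CD8+	HMMR	E405K	0.83	1.04	26.5	False
NL-9	CD8+	C6	A298P	0.80	1.31	23.1	False
NL-9	CD8+	CLIP2	R932H	0.68	0.80	34.0	False
MS-1	CD8+	MBL2	A37S	0.59	1.07	8.9	True
MS-2	CD4+	CD180	D526Y	0.46	0.74	24.4	False
MS-21	CD8+	STAT3	D661Y	0.45	0.70	34.0	False
MS-22	CD8+	INSR	A119V	0.40	0.74	31.0	True
MS-14	CD8+	ITGB3	F229L	0.35	0.46	29.7	False
MS-8	CD8+	TLR7	N275K	0.32	0.53	0.009	True
MS-3	CD8+	MAPK10	S316F	0.23	0.60	22.2	True
MS-12	others	ATM	L2519V	0.19	1.34	26.3	False
MS-23	CD8+	CFH	V407L	0.19	0.56	0.001	True
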