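accession	gene	score	fc_40min	fc_2h	fc_5h	chem_target
Q14566	MCM6	76.01	-4.2	-1.1	-2	1
Q14764	MVP	88.9	-1.2	-1.9	-2.6	0
P35579	MYH9	166.85	-1.7	-2.9	-1.6	1
P61160	ACTR2	60.97	-2.6	-1.4	-1.8	0
Q02338	BDH1	71.17	-1.7	-1.4	-2.6	0
P20290	BTF3	62.09	1.2	-2.9	-1.5	0
Q7L1Q6	BZW1	95.07	-1.3	-3.8	-2.3	0
P17655	CAPN2	101.09	-1.3	-3.1	-1.9	0
A8K010	C6orf176	33.72	-1.1	-3.3	-1.6	0
P53618	COPB1	64.4	-2.9	-1.5	-1.4	0
O60888	CUTA	62.42	1.2	-2.2	-2.9	0
O14976	GAK	47.67	-3.4	-3.8	-2.9	0
O95395	GCNT3	59.62	-3.2	-1.2	-1.6	0
P52306	RAP1GDS1	66.74	-1.2	-3	-1.1	0
O15228	GNPAT	46.58	-4.5	-3.1	-1.9	0
Q86Y56	HEATR2	63.07	-1.5	-5	-1.4	0
Q6YP21	CCBL2	39.9	1.7	OFF	1.5	0
P43243	MATR3	269.16	1	-1.2	-4.5	0
O75439	PMPCB	99.73	-2.9	1.2	-1.1	0
O43847	NRD1	41.16	-1.3	-2.9	1.6	1
O15270	SPTLC2	62.71	-3.2	-2	-2.5	0
P29122	PCSK6	30.52	-1.3	-1.5	-16.7	0
P00491	PNP	91.96	-2	-5.6	1.7	0
P25787	PSMA2	75.42	1.6	-2.9	1	1
O14818	PSMA7	103.36	-1.3	-2.8	-1.1	0
Q13813	SPTAN1	112.76	-1.6	-3.1	-1.6	0
Q9UL25	RAB21	129.33	-2.6	1.1	-1.1	0
Q9NV58	RNF19A	31.17	-1.4	-1.8	-4.8	0
P62081	RPS7	65.3	-4.2	-3.8	-2.6	0
Q96FQ6	S100A16	78	-2.6	-1.4	1	0
P63208	SKP1	72.23	-7.1	-3.1	1.2	0
O00193	SMAP	74.25	-1.5	-2.6	-1.3	0
Q96JX3	SERAC1	32.13	-1.1	1.3	-2.5	0
Q9Y5M8	SRPRB	54.95	-1.7	-1.1	-2.9	0
Q96I99	SUCLG2	85.7	-1.5	-2.4	-2.4	0
O75223	GGCT	37.33	1.1	2	3.8	0
P61758	VBP1	152.64	2.1	2.2	2.5	0
Q9BWD1	ACAT2	69.2	2.5	2	3.2	0
Q86TX2	ACOT1	73.32	2.8	1.6	2.4	0
P02647	APOA1	76.16	1.9	2.7	-1.1	0
O00192	ARVCF	46	ON	ON	ON	0
Q9NYF8	BCLAF1	86.18	1	ON	ON	0
O14523	C2CD2L	31.3	2.9	1.7	2	0
P60953	CDC42	52.58	2.3	1.5	3.1	0
Q9UJS0	SLC25A13	57.95	2.4	3.4	1.9	0
O43809	NUDT21	70.35	1.2	-1.7	2.5	0
Q96C86	DCPS	70.59	1.5	2.1	2.4	1
Q5TDH0	DDI2	31.55	1	ON	ON	0
P18858	LIG1	49.53	2.3	2.2	2.6	0
Q5JZY3	EPHA10	37.22	ON	ON	ON	0
O76003	GLRX3	50.31	3.2	1.8	2.4	0
Q14103	HNRNPD	138.39	1.4	3	1.4	0
Q96P70	IPO9	88.04	3.9	2.9	2.9	1
P33176	KIF5B	102.25	4.3	3.6	5.1	1
P49006	MARCKSL1	112.06	ON	ON	1	0
Q9H3R2	MUC13	68.36	1.8	4.2	1.9	0
Q7Z406	MYH14	90.59	-1.1	9.7	-1.9	0
Q9NX40	OCIAD1	87.8	2.6	2.9	2.3	0
Q15102	PAFAH1B3	84.5	2.4	62.4	1.6	0
O43252	PAPSS1	51.9	1	1	ON	0
P36871	PGM1	105.24	3.3	-2.2	2.2	0
P35232	PHB	90.52	8.4	4.7	3.2	0
Q9UHJ6	SHPK	59.09	1	1	ON	0
P52788	SMS	60.56	-1.2	2.1	3.2	0
Q01082	SPTBN1	63.84	ON	ON	ON	0
Q9Y3F4	STRAP	80.3	2.9	3.7	4.5	0
P26640	VARS	54.77	1.7	3	3.5	1
Q86VP1	TAX1BP1	31.29	2.3	11.7	1.2	0
Q9HD45	TM9SF3	71.54	1.5	3.1	-1.8	0
P55327	TPD52	64.69	5.9	1.8	1.8	0
P38606	ATP6V1A	66.31	-1.2	4.4	2.8	0
P45880	VDAC2	59.14	2.1	4	2	0
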