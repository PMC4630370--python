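accession	gene	score	empai
O95218	ZRANB2	39	0.21
Q9NX65	ZSCAN32	26	0.05
Q9UBQ0	VPS29	56	0.66
Q14376	GALE	38	0.1
Q12888	TP53BP1	28	0.02
O14773	TPP1	76	0.06
Q13428	TCOF1	27	0.02
P04183	TK1	24	0.15
Q9NXG2	THUMPD1	58	0.09
Q8WW59	SPRYD4	39	0.16
P63151	PPP2R2A	87	0.07
Q9NVA2	SEPT11	29	0.08
O00764	PDXK	59	0.11
Q16740	CLPP	67	0.26
Q9Y4X5	ARIH1	29	0.06
O15460	P4HA2	41	0.12
P40261	NNMT	46	0.27
P19105	MYL12A	200	2.45
Q16539	MAPK14	82	0.19
Q9UNF1	MAGED2	238	0.18
P50213	IDH3A	64	0.2
P05161	ISG15	34	0.21
O00629	KPNA4	49	0.06
Q8WTS6	SETD7	42	0.09
P06737	PYGL	40	0.04
P30712	GSTT2	96	0.14
P47755	CAPZA2	109	0.38
P52907	CAPZA1	118	0.54
P41091	EIF2S3	43	0.07
O95571	ETHE1	35	0.13
Q9BVJ7	DUSP23	50	0.23
P52564	MAP2K6	29	0.1
Q14691	GINS1	24	0.16
Q3LXA3	DAK	45	0.06
P21291	CSRP1	47	0.39
Q99627	COPS8	69	0.35
Q9UBW8	COPS7A	46	0.12
P61201	COPS2	136	0.23
Q07021	C1QBP	648	1.74
Q9NT62	ATG3	58	0.1
Q9BZZ5	API5	173	0.13
P12814	ACTN1	1345	1.76
P11766	ADH5	78	0.19
P36404	ARL2	38	0.4
P40616	ARL1	39	0.19
P84077	ARF1	99	0.66
P00813	ADA	35	0.09
Q9BTT0	ANP32E	169	0.41
P84098	RPL19	38	0.16
P61586	RHOA	32	0.17
Q07960	ARHGAP1	63	0.07
Q14657	LAGE3	34	0.26
Q96IU4	ABHD14B	67	0.17
P39687	ANP32A	286	1.38
O75607	NPM3	33	0.2
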