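rank	protein	degree	betweenness	closeness	is_seed
1	CASP3	45	0.219802	0.372358	1
2	TGFB1	21	0.105624	0.286967	1
3	CTNNB1	15	0.095291	0.379139	0
4	CD4	9	0.087143	0.298956	0
5	SRC	28	0.074667	0.391453	0
6	CASP8	21	0.072508	0.340774	0
7	UBC	40	0.071289	0.382304	0
8	EGFR	22	0.067592	0.373573	0
9	AGT	11	0.066604	0.250273	1
10	APP	7	0.052618	0.311141	0
11	SHC1	23	0.051452	0.370550	0
12	TGFBR2	8	0.051187	0.329496	0
13	IGF1R	22	0.050850	0.348554	1
14	CBL	27	0.048630	0.369355	0
15	PIK3R1	25	0.047302	0.377265	0
16	LCK	20	0.045433	0.353395	0
17	SNCA	6	0.044806	0.337261	0
18	AGTR1	5	0.041871	0.286250	0
19	CREBBP	14	0.041003	0.333333	0
20	PTPN11	19	0.036798	0.360063	0
21	TNF	29	0.036016	0.344361	1
22	FYN	22	0.035117	0.358372	0
23	CASP1	2	0.034475	0.256726	0
24	CDC5L	12	0.034223	0.298177	0
25	TGFBR1	8	0.033620	0.322535	0
26	CCR5	10	0.033599	0.253039	1
27	CBLB	26	0.033107	0.355590	1
28	RELA	15	0.032008	0.330925	0
29	STAT3	16	0.030426	0.340267	0
30	UBB	30	0.028880	0.360063	0
31	NOS2	5	0.026136	0.296632	1
32	CTLA4	7	0.026063	0.287688	1
33	IL18	4	0.026048	0.205566	1
34	TOR1A	4	0.026048	0.254162	1
35	SYK	16	0.025902	0.333819	0
36	ESR1	9	0.025628	0.337261	0
37	BIRC2	22	0.024823	0.346970	0
38	MAPK14	9	0.024158	0.350153	0
39	CAV1	11	0.023528	0.342814	0
40	TRAF2	28	0.023094	0.342302	0
41	ZAP70	12	0.022875	0.340267	0
42	ARRB1	6	0.021873	0.303311	0
43	UBE2I	8	0.021765	0.327611	0
44	NFKBIA	13	0.020635	0.360630	0
45	IL16	2	0.020558	0.290609	0
46	PRKCD	12	0.020103	0.353941	0
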