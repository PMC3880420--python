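tag_id	function	family	top_mean	top_lo	top_hi	middle_mean	middle_lo	middle_hi	bottom_mean	bottom_lo	bottom_hi	p_printed	fold_printed	fold_lo	fold_hi
23641	Endocellulase	GH5,CBM1	6	0	14	41	0	123	370	150	591	0.021	57.9	25.21	268.15
16339	Endocellulase	GH5	96	13	178	28	0	60	140	56	224	0.025	1.5	0.71	3.98
10483	Cellobiohydrolase (CBHI-I)	GH7,CBM1	14	0	28	56	0	158	524	349	698	2.2e-3	36.4	20.10	107.96
24891	Cellobiohydrolase (CBHI-II)	GH7	449	13	885	51	0	137	1211	911	1512	2.2e-4	2.7	1.53	8.43
20092	beta-Glucosidase, intracellular	GH3	23	1	45	12	0	33	58	38	79	7.2e-3	2.6	1.41	7.54
2990	Lytic polysaccharide monooxygenase	AA9	0	0	0	21	0	60	96	53	140	0	NA	NA	NA
323	Xylanase	GH10,CBM1	7	0	21	92	0	274	669	360	977	8.0e-3	101.3	35.68	1089.35
7614	Acetyl xylan esterase	CE1,CBM1	88	38	137	175	0	395	1168	917	1419	3.0e-4	13.3	9.12	22.92
18781	Xyloglucanase	GH12	16	1	31	95	70	119	141	0	287	4.3e-4	8.8	2.32	29.17
29382	Xyloglucanase	GH74,CBM1	85	5	164	41	0	100	540	324	756	2.0e-3	6.4	3.48	18.33
17822	Pectinesterase	CE8	77	0	159	39	0	81	209	128	290	4.9e-3	2.7	1.43	10.17
24998	Pectinesterase	CE8	529	295	763	435	297	572	698	304	1092	0.25	1.3	0.75	2.19
13889	Polygalacturonase	GH28	403	273	533	386	244	527	686	418	954	0.075	1.7	1.16	2.43
16820	Pectate lyase	PL1	34	11	56	19	0	57	189	10	368	0.11	5.6	1.88	12.58
25523	Pectate lyase	PL1	222	74	370	146	0	381	704	547	860	8.5e-4	3.2	2.06	6.01
12708	Pectate lyase	PL3	6	0	17	54	0	160	655	398	912	4.1e-3	116.9	45.09	1220.07
29370	Rhamnogalacturonan lyase	PL4	208	87	329	259	125	392	757	477	1036	6.0e-3	3.6	2.28	6.45
17541	Endo-1,5-alpha-L-arabinanase	GH43	141	22	260	81	31	131	204	110	297	0.043	1.4	0.79	3.63
17220	Glucoamylase	GH15,CBM20	32	1	62	35	0	107	130	113	146	8.6e-4	4.1	2.40	11.80
26445	alpha-Galactosidase	GH27	162	79	245	163	93	233	660	578	742	5.7e-6	4.1	2.96	6.40
10080	Cutinase	-	433	0	889	367	156	577	960	743	1177	2.4e-3	2.2	1.24	7.86
28797	Cutinase	-	211	0	444	242	0	555	468	340	596	0.067	2.0	1.18	9.25
14730	Esterase/lipase	-	2	0	7	31	0	88	357	298	416	9.9e-5	148.6	65.90	1290.24
1743	Lipase	-	144	28	259	595	424	765	718	423	1013	6.7e-4	5.0	2.78	12.01
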