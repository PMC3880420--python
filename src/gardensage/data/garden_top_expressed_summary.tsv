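tag_id	function	top_mean	top_lo	top_hi	middle_mean	middle_lo	middle_hi	bottom_mean	bottom_lo	bottom_hi	p_printed
14513	Cerato-platanin-related secreted protein	4918	3465	6370	7389	0	15778	4459	3571	5347	0.51
6186	Cyclophilin (peptidyl-prolyl cis-trans isomerase)	2818	2029	3607	3764	2535	4993	2628	2333	2922	0.10
22660	Conserved hypothetical protein	3196	1902	4489	1554	401	2707	1427	811	2043	0.042
21633	NADH-quinone oxidoreductase	2680	2014	3346	2851	1744	3958	1477	1122	1831	7.1e-3
28405	Hydrophobic surface binding protein	2445	957	3933	1108	715	1501	1893	1488	2298	0.011
20658	Phosphate transporter	917	377	1457	2124	891	3356	2293	1253	3333	0.027
19506	Laccase small subunit	2044	1208	2881	1578	1202	1955	433	336	529	4.9e-4
3396	Laccase	1757	860	2655	507	320	693	210	161	258	4.0e-3
3360	Ubiquitin conjugating enzyme	1709	1389	2030	1583	1161	2005	1393	752	2035	0.51
24891	Cellobiohydrolase (CBHI-II) [GH7]	449	13	885	51	0	137	1211	911	1512	2.2e-4
7614	Acetyl xylan esterase [CE1]	88	38	137	175	0	395	1168	917	1419	3.0e-4
19652	Glutathione S-transferase	1147	701	1592	998	726	1271	889	633	1146	0.43
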