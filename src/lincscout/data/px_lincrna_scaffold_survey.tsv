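scaffold_id	scaffold_length_bp	n_known_genes	n_lincrna	min_length_bp	max_length_bp	mean_length_bp
Scaffold_51	2546611	115	40	202	4513	1268
Scaffold_14	3424285	159	37	222	4001	1153
Scaffold_7	2281484	93	33	221	4544	1099
Scaffold_16	3493687	165	32	206	5659	1028
Scaffold_109	2311385	79	32	214	4763	1314
Scaffold_15	2764502	142	29	201	4806	1188
Scaffold_10	2295158	103	29	206	4171	892
Scaffold_11	1785983	60	29	208	5642	1512
Scaffold_31	2511109	84	28	246	2619	862
Scaffold_5	1890696	51	27	212	5103	1332
Scaffold_21	2450764	93	25	276	4359	1090
Scaffold_12	1974453	61	24	200	4714	1183
Scaffold_52	1725502	70	24	204	5203	1361
Scaffold_8	2584131	109	22	210	7301	2595
Scaffold_4	2074850	79	22	205	3210	928
Scaffold_199	1392491	54	22	210	9894	1311
Scaffold_30	2356637	126	20	220	5718	1192
Scaffold_102	1646965	64	20	203	4765	1259
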