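probe_id	symbol	logFC	AveExpr	p_value	p_adj
ILMN_3103896	Timp1	2.04	8.75	5.21E-26
ILMN_2769918	Timp1	2.03	8.69	1.08E-25
ILMN_1246800	Serpina3n	2.01	9.15	4.24E-24
ILMN_2654624	AI593442	1.88	8.00	7.90E-28
ILMN_1223317	Lgals3	1.82	8.65	9.73E-26
ILMN_2648669	Gpnmb	1.61	6.97	1.92E-12
ILMN_1239726	Snai3	-1.51	7.03	3.60E-26
ILMN_2690603	Spp1	1.31	5.36	4.40E-11
ILMN_2997494	Lox	1.30	6.91	2.97E-17
ILMN_1218235	Gnb3	-1.19	6.81	1.35E-25
ILMN_1232261	Catnal1	1.18	11.00	7.77E-29
ILMN_1226472	Retnla	-1.17	6.51	6.30E-17
ILMN_2975345	Cdo1	1.17	7.84	5.48E-11
ILMN_3127595	BC020188	1.14	6.55	4.28E-21
ILMN_2666312	BC025833	-1.09	8.77	1.90E-21
ILMN_2844820	Angptl7	1.09	7.80	2.58E-07
ILMN_2625279	Pacrg	1.09	6.78	8.73E-28
ILMN_2950622	Arhgdig	1.07	6.09	2.23E-28
ILMN_3091003	Ms4a7	1.05	7.41	1.14E-22
ILMN_1238886	Ccl8	1.04	6.34	1.82E-11
ILMN_1222196	2310007A19Rik	1.03	6.82	1.20E-23
ILMN_2968211	Lgals4	-1.03	9.78	1.15E-14
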