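probe_id	symbol	cor	p_value
ILMN_2698449	Dtr	0.433	2.6E-05
ILMN_2768087	Col6a1	0.429	3.1E-05
ILMN_2636424	Itgbl1	0.414	6.2E-05
ILMN_2818294	Srpx2	0.410	7.3E-05
ILMN_2883952	1810015A11Rik	0.410	7.3E-05
ILMN_2887408	Galr3	0.406	8.6E-05
ILMN_2597831	Cacna1c	-0.403	9.9E-05
ILMN_2748402	Col5a1	0.398	1.2E-04
ILMN_2603958	9130427A09Rik	0.391	1.6E-04
ILMN_2721149	Arl11	0.389	1.8E-04
ILMN_2946873	D030070L09Rik	0.388	1.9E-04
ILMN_2638256	Tex16	-0.379	2.7E-04
ILMN_1259388	Col6a1	0.378	2.8E-04
ILMN_2711163	Ctsk	0.378	2.8E-04
ILMN_2811421	Matk	0.377	2.9E-04
ILMN_2782964	Enpp1	0.376	3.1E-04
ILMN_2664660	Aldh5a1	-0.375	3.2E-04
ILMN_2690603	Spp1	0.374	3.4E-04
ILMN_3136561	Sparc	0.373	3.4E-04
ILMN_1232884	Sphk1	0.371	3.7E-04
ILMN_2750201	1700023I07Rik	0.370	3.8E-04
ILMN_2975345	Cdo1	-0.370	3.8E-04
ILMN_2641956	Nab2	-0.370	3.9E-04
ILMN_2833163	BC064033	0.369	4.0E-04
ILMN_2613601	2010001M09Rik	-0.367	4.3E-04
ILMN_1231851	Enpp1	0.365	4.6E-04
ILMN_2953515	Aldh3b1	0.365	4.7E-04
ILMN_1223552	Fbn1	0.365	4.8E-04
ILMN_2645526	Abcc8	-0.363	5.1E-04
ILMN_2614655	Gpnmb	0.363	5.2E-04
ILMN_1214571	Cd109	0.361	5.5E-04
ILMN_1225835	Mfap5	0.360	5.6E-04
ILMN_2702704	Ndufv1	-0.359	5.9E-04
ILMN_2725484	Padi4	0.359	6.0E-04
ILMN_2691951	Polydom	0.358	6.2E-04
ILMN_1221611	Pitpn	0.357	6.3E-04
ILMN_1228485	Csnk2a2	-0.356	6.6E-04
ILMN_2838317	Pqlc3	0.356	6.6E-04
ILMN_1221800	Gabpa	-0.356	6.6E-04
ILMN_2646254	1700102P08Rik	-0.356	6.6E-04
ILMN_3022719	Wiz	-0.355	6.8E-04
ILMN_2453695	Urod	-0.353	7.5E-04
ILMN_2837100	Gm128	0.352	7.6E-04
ILMN_3116885	Gpr137b	0.352	7.7E-04
ILMN_2487358	Eif3s6	0.351	8.1E-04
ILMN_2671755	Ceecam1	0.351	8.1E-04
ILMN_2492500	Zfhx1a	0.351	8.1E-04
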