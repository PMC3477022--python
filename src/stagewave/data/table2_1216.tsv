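contig_id	length_bp	total_reads	group_reads	arabidopsis_hit	description	secondary_description	e_value
1561	899	1684	1221	No hits found			
504	1593	1167	855	AT5G47120	ATBI1 (BAX INHIBITOR 1)		1.0E-109
2496	1641	1319	810	AT2G02760	ATUBC2 (UBIQUITING-CONJUGATING ENZYME 2)		9.0E-86
2811	1259	1273	694	AT1G07890	APX1 (ascorbate peroxidase 1); L-ascorbate peroxidase		1.0E-119
493	3235	1307	679	No hits found		hypothetical protein [Vitis vinifera]	8.0E-37
1702	874	685	607	AT5G59720	HSP18.2 (heat shock protein 18.2)		2.0E-69
2864	1409	870	578	AT2G43750	OASB (O-ACETYLSERINE (THIOL) LYASE B); cysteine synthase		1.0E-142
1551	2577	765	558	AT5G19150	carbohydrate kinase family		1.0E-135
54	1237	1084	538	AT2G23090	unknown protein		4.0E-35
410	1047	1055	518	AT1G13950	ELF5A-1 (EUKARYOTIC ELONGATION FACTOR 5A-1)		6.0E-79
296	1842	750	516	AT3G44110	ATJ3; heat shock protein DNAJ homolog, protein binding		0.0
281	1330	1094	532	AT5G20720	CPN20 (CHAPERONIN 20); calmodulin binding		6.0E-98
2649	1071	1017	502	AT2G21660	CCR2 (COLD, CIRCADIAN RHYTHM, AND RNA BINDING 2)		7.0E-44
2541	2197	740	483	AT3G48000	ALDH2B4; 3-chloroallyl aldehyde dehydrogenase		0.0
698	1330	950	477	AT5G22080	DNAJ heat shock N-terminal domain-containing protein		1.0E-112
1568	1292	515	470	AT5G12020	HSP17.6II (17.6 KDA CLASS II HEAT SHOCK PROTEIN)		7.0E-49
1606	1153	687	455	AT2G43750	OASB (O-ACETYLSERINE (THIOL) LYASE B); cysteine synthase		1.0E-121
2828	1099	640	435	AT1G51200	zinc finger (AN1-like) family protein		4.0E-51
2414	869	613	432	AT3G16640	TCTP (TRANSLATIONALLY CONTROLLED TUMOR PROTEIN)		2.0E-70
2054	595	551	427	No hits found			
2219	882	546	411	No hits found		26 kDa phloem lectin [Cucumis sativus]	4.0E-83
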