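contig_id	length_bp	total_reads	group_reads	arabidopsis_hit	description	secondary_description	e_value
3064	960	1162	776	AT5G22430	unknown protein		1.0E-25
3334	1146	832	505	AT3G46040	RPS15AD (ribosomal protein S15A D)		2.0E-27
1282	680	980	490	No hits found			
1650	1644	514	404	AT5G33370	GDSL-motif lipase/hydrolase family protein		1.0E-146
3111	1010	886	349	No hits found		phloem filament protein; PP1; phloem protein 1 [Cucurbita maxima]	1.0E-25
424	912	1035	331	AT5G59880	ADF3 (ACTIN DEPOLYMERIZING FACTOR 3); actin binding		5.0E-63
153	715	766	317	No hits found			
12937	953	418	312	AT4G15630	integral membrane family protein		3.0E-37
11169	949	792	284	AT1G28330	DYL1 (DORMANCY-ASSOCIATED PROTEIN-LIKE 1)		3.0E-41
2993	1046	494	270	No hits found			
2805	767	757	267	No hits found			
13496	951	687	267	No hits found			
2700	654	428	263	AT5G38650	proteasome maturation factor UMP1 family protein		2.0E-61
2357	598	526	261	No hits found			
1468	899	821	244	AT1G51200	zinc finger (AN1-like) family protein		8.0E-53
2350	973	551	242	AT1G11530	ATCXXS1; protein disulfide isomerase		2.0E-37
3297	1632	729	242	AT3G26960	unknown protein		8.0E-35
3067	1145	744	240	AT2G10940	protease inhibitor/seed storage/lipid transfer protein (LTP) family protein		5.0E-61
342	928	717	225	AT3G26960	unknown protein		2.0E-43
456	830	645	223	No hits found			
485	1612	919	220	AT1G09690	60S ribosomal protein L21 (RPL21C)		1.0E-81
924	1025	673	214	AT4G37300	MEE59 (maternal effect embryo arrest 59)		5.0E-24
1445	1372	514	203	AT5G65020	ANNAT2 (Annexin Arabidopsis 2); calcium ion binding		1.0E-131
620	1165	472	199	AT3G10210	unknown function		1.0E-94
2771	1339	491	195	No hits found			
489	829	799	192	AT1G79040	PSBR (photosystem II subunit R)		4.0E-56
3147	950	593	192	AT4G14305	unknown function		1.0E-62
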