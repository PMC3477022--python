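contig_id	length_bp	total_reads	group_reads	arabidopsis_hit	description	secondary_description	e_value
3017	2294	1346	1269	AT1G08450	CRT3 (CALRETICULIN 3); calcium ion binding/unfolded protein binding		0.0
2794	1211	1482	1100	AT4G35100	PIP3 (PLASMA MEMBRANE INTRINSIC PROTEIN 3); water channel		1.0E-139
1157	739	1256	792	AT1G26880	60S ribosomal protein L34 (RPL34A)		2.0E-59
2093	1884	1133	721	AT5G62700	TUB3; GTP binding/GTPase/structural molecule		0.0
2075	637	1185	657	AT2G21580	40S ribosomal protein S25 (RPS25B)		3.0E-51
886	1337	1195	633	AT3G55440	TPI (TRIOSEPHOSPHATE ISOMERASE); triose-phosphate isomerase		1.0E-119
2327	1622	858	615	AT4G27440	PORB (PROTOCHLOROPHYLLIDE OXIDOREDUCTASE B		0.0
3154	1085	1136	611	AT1G67430	60S ribosomal protein L17 (RPL17B)		1.0E-86
885	1370	951	605	AT2G30620	histone H1.2		1.0E-66
2351	608	1093	579	AT3G61110	ARS27A (ARABIDOPSIS RIBOSOMAL PROTEIN S27)		7.0E-46
2804	1198	1072	575	AT3G04840	40S ribosomal protein S3A (RPS3aA)		1.0E-126
2255	888	1075	566	AT4G40030	histone H3.2		4.0E-72
192	1383	701	522	AT1G18250	ATLP-1; thaumatin-like protein		1.0E-115
2894	744	641	518	AT5G59970	histone H4		2.0E-53
2685	1054	788	497	AT5G39850	40S ribosomal protein S9 (RPS9C)		1.0E-102
606	1477	756	492	No hits found			
1038	1121	948	484	AT3G53740	60S ribosomal protein L36 (RPL36B)		8.0E-45
820	702	783	481	AT5G50460	protein transport protein SEC61 gamma subunit, putative		9.0E-32
107	714	670	474	AT5G59970	histone H4		1.0E-53
1260	801	867	463	AT5G56710	60S ribosomal protein L31 (RPL31C)		3.0E-54
5501	1223	912	459	AT3G52590	UBQ1 (UBIQUITIN EXTENSION PROTEIN 1)		1.0E-68
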