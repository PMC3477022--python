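reads	contig_id	length_bp	hit_id	description	e_value
1222	2152	815	gi|22023939	26 kDa phloem protein [Cucumis sativus]	2.0E-89
886	3111	1010	gi|1753099	phloem filament protein; PP1; phloem protein 1 [Cucurbita maxima]	1.0E-25
546	2219	882	gi|21952270	26 kDa phloem lectin [Cucumis sativus]	4.0E-83
438	1685	625	gi|1669529	CRG16 (gibberelin responsive) [Cucumis sativus]	4.0E-27
315	372	825	gi|21745319	17 kDa phloem lectin [Cucumis sativus]	4.0E-62
312	1342	678	gi|21952272	phloem lectin [Cucurbita argyrosperma subsp. sororia]	8.0E-42
257	1071	857	gi|33415266	poly(A)-binding protein C-terminal interacting protein 6 [Cucumis sativus]	1.0E-72
139	4582	965	gi|21686470	26 kDa phloem lectin [Cucumis melo]	1.0E-55
130	2648	1894	gi|219567000	galactose-binding type-2 ribosome-inactivating protein [Momordica charantia]	1.0E-130
129	2280	668	gi|94450551	pathogen induced 4 protein [Cucumis sativus]	9.0E-32
112	5677	1666	gi|148270942	expressed protein [Cucumis melo]	1.0E-174
77	6868	575	gi|2406582	pathogen-induced protein CuPi1 [Cucumis sativus]	4.0E-46
62	6937	620	gi|2576407	seed nucellus-specific protein [Citrullus lanatus]	2.0E-40
54	3108	803	gi|21745319	17 kDa phloem lectin [Cucumis sativus]	5.0E-88
51	3170	696	gi|169219257	putative Gly-rich RNA-binding protein [Cucumis sativus]	4.0E-49
48	1586	901	gi|21686470	26 kDa phloem lectin [Cucumis melo]	4.0E-31
42	2896	563	gi|51537955	beta-caryophyllene synthase [Cucumis sativus]	2.0E-52
37	2099	733	gi|58263793	profilin [Cucumis melo]	1.0E-29
33	5950	1288	gi|28558780	gag-protease polyprotein [Cucumis melo]	1.0E-80
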