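marker_id	rsid	chrom	pos	alleles
5	rs568000255	12	111390389	-/T
5	rs148177611	12	111390454	AGAA/-
7	rs587641570	14	106091681	-/TGGGCACGG
7	rs35171885	14	106091743	A/-
9	rs587619205	14	106132379	AGG/-
9	rs72033070	14	106132423	TG/-
9	rs587723906	14	106132479	AGG/-
13	rs576201582	14	106267547	AA/-
13	rs571755931	14	106267673	-/GAACCACGGACAGC
17	rs367879758	6	29893482	T/-
17	rs145760005	6	29893549	AAAC/-
24	rs9281938	6	32576282	-/A
24	rs66715534	6	32576384	AAG/-
29	rs71848820	6	29906220	TACC/-
29	rs535382238	6	29906247	-/AC
29	rs372209280	6	29906267	AA/-
29	rs551483768	6	29906274	AATT/-
29	rs113403777	6	29906356	AT/-
30	rs113251661	6	29920335	-/T
30	rs28993377	6	29920400	CT/-
30	rs139015681	6	29920487	AAAG/-
31	rs535742949	6	29921529	-/G
31	rs111867975	6	29921542	C/-
31	rs139686584	6	29921679	GAA/-
38	rs573698459	11	101349079	T/-
38	rs113869189	11	101349205	-/TTCCCCTCCTCTTG
38	rs572328951	11	101349248	AAAT/-
46	rs58621233	14	106175037	-/ATGCCATG
46	rs59809572	14	106175040	-/CCAGGAGGACAG
46	rs587739978	14	106175045	-/G
52	rs9279904	6	32608168	AT/-
52	rs139765606	6	32608178	A/-
52	rs146682150	6	32608282	-/A
52	rs531139227	6	32608334	AAA/-
52	rs140779686	6	32608357	-/A
52	rs148817405	6	32608392	-/T
52	rs67106675	6	32608459	A/-
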