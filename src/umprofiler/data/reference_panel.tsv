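#umprofiler-panel	amplicon_count=418
#regions	chrom	start	end	gene	pool	mode
1	93297600	93307400	RPL5	1	FULL_CDS
2	198266700	198267550	SF3B1	2	HOTSPOT
3	52435021	52444121	BAP1	1	FULL_CDS
4	104030600	104122100	CENPE	2	FULL_CDS
7	140453075	140453193	BRAF	1	HOTSPOT
9	80409373	80409532	GNAQ	2	HOTSPOT
9	21967752	21975132	CDKN2A	1	FULL_CDS
13	49280660	49280860	CYSLTR2	2	HOTSPOT
13	41129805	41240730	FOXO1	1	FULL_CDS
14	62162120	62214975	HIF1A	2	FULL_CDS
17	74730200	74733490	SRSF2	1	FULL_CDS
17	7571721	7590863	TP53	2	FULL_CDS
19	3118922	3119090	GNA11	1	HOTSPOT
20	9389510	9389700	PLCB4	2	HOTSPOT
X	20156560	20156760	EIF1AX	1	HOTSPOT
#snps	rsid	chrom	arm	pos
rs2000101	1	p	12012345
rs2000108	1	p	23790122
rs2000115	1	p	35567899
rs2000122	1	p	47345676
rs2000129	1	p	59123453
rs2000136	1	p	70901230
rs2000143	1	p	82679007
rs2000150	1	p	94456784
rs2000157	1	p	106234561
rs2000164	1	q	150012345
rs2000171	1	q	160012345
rs2000178	1	q	170012345
rs2000185	1	q	180012345
rs2000192	1	q	190012345
rs2000199	1	q	200012345
rs2000206	1	q	210012345
rs2000213	1	q	220012345
rs2000220	1	q	230012345
rs2000227	3	p	5012345
rs2000234	3	p	13312345
rs2000241	3	p	21612345
rs2000248	3	p	29912345
rs2000255	3	p	38212345
rs2000262	3	p	46512345
rs2000269	3	p	54812345
rs2000276	3	p	63112345
rs2000283	3	p	71412345
rs2000290	3	p	79712345
rs2000297	3	q	95012345
rs2000304	3	q	106123456
rs2000311	3	q	117234567
rs2000318	3	q	128345678
rs2000325	3	q	139456789
rs2000332	3	q	150567900
rs2000339	3	q	161679011
rs2000346	3	q	172790122
rs2000353	3	q	183901233
rs2000360	8	p	3012345
rs2000367	8	p	7345678
rs2000374	8	p	11679011
rs2000381	8	p	16012344
rs2000388	8	p	20345677
rs2000395	8	p	24679010
rs2000402	8	p	29012343
rs2000409	8	p	33345676
rs2000416	8	p	37679009
rs2000423	8	q	50012345
rs2000430	8	q	60456789
rs2000437	8	q	70901233
rs2000444	8	q	81345677
rs2000451	8	q	91790121
rs2000458	8	q	102234565
rs2000465	8	q	112679009
rs2000472	8	q	123123453
rs2000479	8	q	133567897
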