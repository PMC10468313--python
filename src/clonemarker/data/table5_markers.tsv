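Cultivar	Clone ID	Marker ID	DNA variant	Scaffold/start position (bp)	Allele length (bp)
CH	95	CH95_2	InDel	GC_411/17,831,79	180/190
CH	95	CH95_3	InDel	GC_595/23,803,897	194/201
CH	95	CH95_4	InDel	GC_677/30,351	229/240
CH	76	CH76_1	InDel	GC_478/6,101,20	461/487
CH	76	CH76_2	InDel	GC_413/11189702	325/344
CH	76	CH76_4	InDel	GC_472/14,106,797	238/243
CH	548	CH548_1	InDel	GC_413/33,977,545	392/399
CH	548	CH548_2	InDel	GC_595/10,809,953	225/235
CH	548	CH548_3	InDel	GC_140/4,753,007	247/256
CH	548	CH548_4	InDel	GC_648/23,853	146/154
SB	242	SB242_2	InDel	scaffold_340/10,773,980	181/156
SB	242	SB242_3	SNV G/A	scaffold_356/1,788,235	249
SB	242	SB242_5	SNV C/T	scaffold_326/3,712,137	209
SB	1	SB1_5	InDel	scaffold_347/8,417,924	175/164
SB	1	SB1_7	InDel	scaffold_312/849,432	183/180
SB	1	SB1_8	InDel	scaffold_20/302,238	195/186
SB	1	SB1_9	InDel	scaffold_348/441,728	250/220
SB	159	SB15_1	SNV G/A	scaffold_320/11,246,529	218
SB	159	SB159_3	InDel	scaffold_283/7,733,780	176/187
SB	159	SB159_5	SNV G/A	scaffold_187/9,263,435	167
SB	107	SB107_1	InDel	scaffold_87/7,203,360	221/217
SB	107	SB107_3	InDel	scaffold_340/7,767,043	240/242
SB	107	SB107_6	InDel	scaffold_11/1,681,496	245/230
SB	530	SB530_3	InDel	scaffold_271/195,088	182/176
SB	530	SB530_7	InDel	scaffold_8/17,091,159	246/255
SB	530	SB530_9	InDel	scaffold_283/9,918,472	188/175
CS	46	CS46_1	InDel	000028F/1,708,937	141/153
CS	46	CS46_2	InDel	000078F/2,184,324	156/168
CS	46	CS46_4	InDel	000028F/3,575,774	145/153
CS	169	CS169_2	SNV T/A	000119F/1,481,484	230
CS	169	CS169_3	SNV A/G	000280F/294,173	150
CS	169	CS169_4	InDel	000204F/233,732	194/195
CS	338	CS338_2	SNV C/T	000017F/732,204	165
CS	338	CS338_6	InDel	000212F/205,063	293/299
M	348	M348_1	InDel	GcS596/405,864	165/178
M	348	M348_2	InDel	GcS648/645,734	235/238
M	348	M348_3	SNV A/T	GcS472/1,346,008	180
M	348	M348_4	SNV G/A	GcS111/3,645,198	250
M	181	M181_1	InDel	GcS645/107,657	244/249
M	181	M181_2	InDel	GcS591/510,148	198/203
M	181	M181_3	SNV A/G	GcS828/184,353	246
M	181	M181_4	SNV C/T	GcS1310/197,649	212
M	346	M346_2	InDel	GcS1195/341,995	229/236
M	346	M346_3	InDel	GcS1246/39,718	176/184
M	346	M346_4	InDel	GcS1004/2,348,379	313/328
M	346	M346_5	InDel	GcS145/215,538	176/192
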