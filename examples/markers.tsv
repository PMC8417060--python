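marker_id	chrom	pos_bp	maternal_a	maternal_b	paternal
SYN0001	Chr19	337481	163	173	199,267
SYN0002	Chr19	348302	178	216	167,191
SYN0003	Chr19	392198	185	269	247,265
SYN0004	Chr19	564671	144	148	276,305
SYN0005	Chr19	1350842	252	279	170,207
SYN0006	Chr19	1355996	158	308	165
SYN0007	Chr19	1819791	179	296	184
SYN0008	Chr19	1955447	171	202	167
SYN0009	Chr19	2060823	252	256	163,255
SYN0010	Chr19	2221074	148	233	270,315
SYN0011	Chr19	2295804	170	231	145,221
SYN0012	Chr19	2378837	205	255	190,252
SYN0013	Chr19	2738366	183	283	229,253
SYN0014	Chr19	3424932	191	293	145,170
SYN0015	Chr19	3457467	174	312	225,319
SYN0016	Chr19	3739890	261	269	195,262
SYN0017	Chr19	3983449	217	300	207,318
SYN0018	Chr19	4008819	191	272	246
SYN0019	Chr19	4073243	198	319	285
SYN0020	Chr19	4136387	233	303	293
SYN0021	Chr19	4216337	175	187	276
SYN0022	Chr19	4268866	239	310	255
SYN0023	Chr19	4298823	195	196	216,247
SYN0024	Chr19	4433758	226	285	185,216
SYN0025	Chr19	4790144	154	222	195
SYN0026	Chr19	4910037	146	232	290,304
SYN0027	Chr19	5061365	190	216	174,204
SYN0028	Chr19	5069584	204	212	235,296
SYN0029	Chr19	5160704	291	303	208
SYN0030	Chr19	5262961	144	171	299
SYN0031	Chr19	7200629	211	293	221
SYN0032	Chr19	7205726	311	317	207,264
SYN0033	Chr19	7219990	221	234	182
SYN0034	Chr19	7323194	277	288	154,165
SYN0035	Chr19	7468787	159	286	215,251
SYN0036	Chr19	7589789	280	298	172,219
SYN0037	Chr19	7711718	188	298	250,275
SYN0038	Chr19	7790234	146	301	149
SYN0039	Chr19	7922782	165	315	197,311
SYN0040	Chr19	8301504	188	206	303
SYN0041	Chr19	8394480	202	290	148
SYN0042	Chr19	8494374	214	233	224,247
SYN0043	Chr19	9119237	199	278	185,298
SYN0044	Chr19	9261888	240	245	179,237
SYN0045	Chr19	9420163	200	210	261
SYN0046	Chr19	9511360	163	235	311
SYN0047	Chr19	9634489	232	290	156
SYN0048	Chr19	9648535	160	317	233
SYN0049	Chr19	9701916	221	226	220,304
SYN0050	Chr19	9954575	141	313	145
SYN0051	Chr19	10216851	169	299	242,300
SYN0052	Chr19	10330437	181	298	172,303
SYN0053	Chr19	10545854	259	267	277
SYN0054	Chr19	10604109	165	225	193
SYN0055	Chr19	10622292	172	200	180
SYN0056	Chr19	10902157	157	315	149,200
SYN0057	Chr19	11396534	236	243	235,245
SYN0058	Chr19	11479020	276	280	192,230
SYN0059	Chr19	12019152	144	202	246
SYN0060	Chr19	12035471	240	274	206,299
SYN0061	Chr19	12046336	146	208	204
SYN0062	Chr19	12447314	172	179	144
SYN0063	Chr19	12692631	212	278	248,299
SYN0064	Chr19	12728273	216	238	189
SYN0065	Chr19	12731562	153	267	171,295
SYN0066	Chr19	12760579	185	239	215,270
SYN0067	Chr19	13125448	266	281	261,308
SYN0068	Chr19	13502882	199	310	304
SYN0069	Chr19	13518599	159	296	217,307
SYN0070	Chr19	14440950	255	267	167,291
SYN0071	Chr19	14510525	220	276	160
SYN0072	Chr19	14785262	253	291	246,287
SYN0073	Chr19	14866407	188	293	183,222
SYN0074	Chr19	14956000	204	211	271
SYN0075	Chr19	14967972	165	265	168,231
SYN0076	Chr19	15059803	236	279	217
SYN0077	Chr19	15449740	204	248	202,281
SYN0078	Chr19	15478961	160	306	248,291
SYN0079	Chr19	15750850	167	315	232,249
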