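strain	rate_total	rate_snp	rate_indel	true_snp	true_indel	false_snp	false_indel	not_detected
Kashimamugi	94.595	96.465	79.167	191	19	7	5	131
Ishukushirazu	94.492	96.651	77.778	202	21	7	6	117
Misato Golden	94.231	96.774	72.727	180	16	6	6	144
Sayakaze	93.269	96.721	68.000	177	17	6	8	145
Taishomugi	93.133	96.552	70.000	196	21	7	9	119
Fibersnow	93.088	96.216	75.000	178	24	7	8	136
Shunrei	93.074	96.098	69.231	197	18	8	8	119
Ryofu	93.004	96.667	69.697	203	23	7	10	110
Akashinriki	92.991	96.316	66.667	183	16	7	8	139
Sukai Golden	92.829	96.429	62.963	216	17	8	10	102
Harushirane	92.803	95.575	76.316	216	29	10	9	89
Kanto-kawa 98	92.771	96.262	71.429	206	25	8	10	104
Touzan-hadaka 112	92.766	95.522	76.471	192	26	9	8	118
Steptoe	92.641	95.833	76.923	184	30	8	9	121
Minorimugi	92.444	96.277	72.973	181	27	7	10	128
Kashima Goal	92.405	94.175	80.645	194	25	12	6	116
Harumiyabi	92.369	97.748	48.148	217	13	5	14	104
Kanto-kawa 93	92.344	97.143	67.647	170	23	5	11	144
Kanto-kawa 96	92.276	96.602	70.000	199	28	7	12	107
Ichibanboshi	92.116	97.619	54.839	205	17	5	14	112
Haruhimeboshi	91.968	97.235	56.250	211	18	6	14	104
Kanto-kawa 97	91.892	95.699	72.222	178	26	8	10	131
Beaufiber	91.855	95.833	65.517	184	19	8	10	132
Suzukaze	91.837	94.86	70.968	203	22	11	9	108
Yumesakiboshi	91.827	95.402	73.529	166	25	8	9	145
Touzan-kawa 113	91.700	94.931	72.222	206	26	11	10	100
Nishinohoshi	91.525	96.602	56.667	199	17	7	13	117
Kanto-kawa 92	91.469	97.126	64.865	169	24	5	13	142
Silkysnow	91.286	96.517	65.000	194	26	7	14	112
Haruka Nijo	91.200	96.135	67.442	199	29	8	14	103
Sachiho Golden	91.111	95.833	63.636	184	21	8	12	128
Yokozuna	90.517	95.146	53.846	196	14	10	12	120
Shikoku-hadaka 84	90.393	96.447	53.125	190	17	7	15	124
Daishimochi	90.000	96.154	50.000	200	16	8	16	113
Haganemugi	72.959	75.882	53.846	129	14	41	12	156
Amagi Nijo	62.500	64.481	48.000	118	12	65	13	144
Asuka Golden	61.628	64.035	43.333	146	13	82	17	95
Tochinoibuki	58.203	62.441	37.209	133	16	80	27	97
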