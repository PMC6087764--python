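id	name	mw	ob	caco2	dl	mlogp	nhacc	nhdon	tpsa	gi
BZ27	Atractylenolactam	229.32	56.48	1.23	0.15	2.85	1	1	29.1	High
BZ42	Anhydroatractylolide	234.34	52.24	1.24	0.15	3.44	2	0	26.3	High
BZ57	8β-methoxy-atractylenolide I	260.33	54.47	1.02	0.19	2.63	3	0	35.53	High
BZ59	14α-methyl butyryl-14-acetyl-2E,8E,10E-atractylentriol	316.40	64.50	0.20	0.23	2.71	4	2	66.76	High
BZ60	12α-methylbutyryl-14-acetyl-2E,8Z,10E-atractylentriol	358.43	62.69	0.41	0.29	3.07	5	1	72.83	High
BZ64	8β-ethoxyatractylenolide- II	276.38	56.48	1.08	0.21	3.37	3	0	35.53	High
BZ72	Isoasterolide A	232.32	52.65	1.27	0.15	3.35	2	0	26.3	High
BZ75	Atractylenolide VII	262.39	40.99	1.32	0.14	3.84	2	0	26.3	High
BZ83	Atractylodes macrocephala	462.68	45.96	0.85	0.81	2.47	3	1	46.53	High
BZ84	Biatractylolide	462.63	45.96	0.84	0.81	5.43	4	0	52.6	High
BZ100	8β-ethoxy atractylenolide-II	276.38	56.48	1.08	0.21	3.37	3	0	35.53	High
BZ102	Atractylenolide I	230.31	35.21	1.32	0.15	3.26	2	0	26.3	High
BZ107	Atractylone	216.324	25.99	1.74	0.13	3.42	1	0	13.14	High
BZ110	AtractylenolideII	232.32	43.54	1.31	0.15	3.35	2	0	26.3	High
BZ119	3β-acetoxyatractylone	274.36	34.74	1.19	0.22	2.83	3	0	39.44	High
BZ124	14-acetyl-12-senecioyl-2E,8Z,10E-atractylentriol	356.42	63.37	0.26	0.30	2.99	5	1	72.83	High
BZ125	Atractylenolide III	248.32	67.29	0.76	0.17	2.47	3	1	46.53	High
ZS21	8-geranyloxypsoralen	338.4	41.92	1.178	0.418	3.23	4	0	52.58	High
ZS22	5-Geranyloxy-7-Methoxycoumarin	328.4	44.23	1.121	0.300	3.16	4	0	48.67	High
ZS23	Bergamottin	338.4	41.73	1.161	0.421	3.23	4	0	52.58	High
ZS24	Phellopterin	300.31	37.43	0.978	0.279	1.82	5	0	61.81	High
ZS25	Isoimperatorin	270.28	47.54	1.057	0.225	2.14	4	0	52.58	High
ZS26	6′-7′-dihydroxybergamottin	372.41	70.77	0.12	0.52	1.66	6	2	93.04	High
ZS27	Epoxybergamottin	354.4	57.25	0.922	0.523	2.48	5	0	65.11	High
ZS28	Cnidilin	300.31	42.42	0.948	0.280	1.82	5	0	61.81	High
ZS30	Epoxyaurapten	314.38	62.78	0.952	0.309	2.74	4	0	51.97	High
ZS34	Byakangelicin	334.32	34.89	−0.01	0.35	0.29	7	2	102.27	High
ZS35	Heraclenol	304.29	72.63	0.08	0.29	0.57	6	2	93.04	High
ZS36	Oxypeucedanin hydrate	304.29	33.07	−0.06	0.29	0.57	6	2	93.04	High
ZS39	Isoponcimarin	330.37	63.28	0.534	0.313	1.91	5	0	69.04	High
ZS40	Poncimarin	330.37	79.20	0.754	0.350	1.99	5	0	64.5	High
ZS41	Byakangelicol	316.31	45.21	0.760	0.356	1.08	6	0	74.34	High
ZS42	Oxypeucedanin	286.28	66.18	0.870	0.297	1.39	5	0	65.11	High
ZS71	Monohydryoxy-tetramethoxyflavone	358.34	45.38	1.19	0.37	0.4	7	1	87.36	High
ZS73	Diosmetin	300.26	42.87	0.46	0.27	0.22	6	3	100.13	High
ZS75	5-demethylnobiletin	388.37	89.03	1.01	0.48	0.11	8	1	96.59	High
ZS79	Chrysoeriol	300.26	41.60	0.45	0.27	0.22	6	3	100.13	High
ZS82	Sakuranetin	286.28	40.19	0.59	0.24	0.96	5	2	75.99	High
ZS85	Acacetin	284.26	37.69	0.65	0.24	0.77	5	2	79.9	High
ZS86	Isosakuranetin	286.28	37.59	0.58	0.24	0.96	5	2	75.99	High
ZS88	N-methyl tyramine-O-alpha-L-rhamnopyranoside	297.35	36.70	−0.04	0.19	−0.16	6	4	91.18	High
ZS104	Synephrine	167.21	75.25	0.63	0.04	0.65	3	3	52.49	High
ZS105	4-[(2S,3R)-5-[(E)-3-hydroxyprop-1-enyl]-7-methoxy-3-methylol-2,3-dihydrobenzofuran-2-yl]-2-methoxy-phenol	358.39	50.76	0.03	0.39	1.09	6	3	88.38	High
ZS107	5,7,4′-Trimethylapigenin	312.32	39.83	1.01	0.3	1.25	5	0	57.9	High
ZS108	Hesperetin	302.28	47.74	0.28	0.27	0.41	6	3	96.22	High
ZS109	6-Methoxy aurapten	328.4	31.24	1.01	0.3	3.16	4	0	48.67	High
ZS110	Ammidin	270.28	34.55	1.13	0.22	2.14	4	0	52.58	High
ZS115	Naringenin	272.26	59.29	0.28	0.21	0.71	5	3	86.99	High
ZS117	Tetramethoxyluteolin	342.34	43.68	0.96	0.37	0.94	6	0	67.13	High
ZS123	Prangenin	286.28	43.60	0.8	0.29	1.39	5	0	65.11	High
ZS128	Eriodyctiol (flavanone)	288.25	41.35	0.05	0.24	0.16	6	4	107.22	High
ZS130	Hesperidin	610.56	13.33	−2.03	0.67	−3.04	15	8	234.29	Low
ZS131	Isolimonic acid	639.01	48.86	0.43	0.18	4.33	3	1	57.61	High
ZS134	Isosinensetin	372.37	51.15	1.16	0.44	0.63	7	0	76.36	High
ZS135	Sinensetin	372.37	50.56	1.12	0.45	0.63	7	0	76.36	High
ZS137	Luteolin	286.24	36.16	0.19	0.25	−0.03	6	4	111.13	High
ZS143	Naringin	580.53	6.92	−1.99	0.78	−2.77	14	8	225.06	Low
ZS144	Narirutin	580.53	8.15	−1.8	0.75	−2.77	14	8	225.06	Low
ZS145	Neohesperidin_qt	302.28	71.17	0.26	0.27	0.41	6	3	96.22	High
ZS146	Nobiletin	402.39	61.67	1.05	0.52	0.34	8	0	85.59	High
ZS149	Prangenin hydrate	304.29	72.63	0.14	0.29	0.57	6	2	93.04	High
ZS150	Neohesperidin	610.62	11.57	−2.05	0.69	−3.04	15	8	234.29	Low
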