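taxon_id	CK_1	CK_2	CK_3	CK_4	CK_5	CK_6	M_1	M_2	M_3	M_4	M_5	M_6	bioM_1	bioM_2	bioM_3	bioM_4	bioM_5	bioM_6
ASV01	2	2	2	9	0	2	1	0	2	1	0	1	1	2	1	6	4	1
ASV02	5	8	10	16	5	104	106	14	68	7	0	11	22	6	0	9	11	2
ASV03	72	87	15	29	9	22	12	50	5	15	1	202	21	12	1	16	108	8
ASV04	99	110	21	21	46	47	53	45	11	48	5	59	30	9	3	19	38	10
ASV05	4	29	24	24	22	18	56	26	14	8	33	13	8	22	32	39	35	16
ASV06	2	2	3	2	1	5	15	12	39	4	0	1	22	16	0	1	2	1
ASV07	12	54	14	125	99	73	100	57	60	89	83	6	37	86	92	40	67	78
ASV08	12	3	37	3	26	32	7	69	13	5	3	40	21	42	2	40	87	27
ASV09	35	14	33	36	3	145	31	63	82	68	16	26	22	28	47	18	11	3
ASV10	238	127	58	9	36	37	55	77	16	29	4	98	5	13	5	7	224	36
ASV11	7	10	3	13	8	7	36	6	7	5	5	12	21	11	13	5	2	7
ASV12	1	8	0	4	5	1	3	0	3	2	0	0	0	0	1	1	1	1
ASV13	8	47	19	11	75	14	133	9	84	19	19	12	26	29	31	105	9	118
ASV14	3	12	0	1	0	4	5	6	0	1	0	12	15	6	0	1	34	7
ASV15	0	5	1	6	4	2	2	0	6	4	2	1	2	2	11	8	5	3
ASV16	2	2	1	11	0	2	24	2	6	22	1	7	1	3	2	1	5	1
ASV17	347	95	14	62	13	79	161	103	2	79	1	142	230	9	17	12	195	58
ASV18	6	8	18	2	5	17	35	22	41	1	0	86	34	61	2	28	26	35
ASV19	0	0	0	0	2	0	1	0	0	2	1	0	1	0	0	0	0	1
ASV20	5	28	27	153	72	58	32	9	36	24	45	14	13	28	122	25	28	47
ASV21	95	360	45	518	798	195	408	41	103	354	1347	63	230	149	443	665	234	321
ASV22	39	178	213	930	195	100	122	42	195	154	627	96	19	6	105	98	42	198
ASV23	4	11	8	7	10	7	2	3	6	5	1	0	3	2	24	12	7	9
ASV24	36	4	25	62	8	60	15	9	11	24	4	6	7	15	26	8	5	0
ASV25	20	9	68	18	25	128	44	60	44	4	1	56	62	81	2	33	11	52
ASV26	119	20	39	37	57	194	214	54	35	153	47	31	81	17	113	17	17	6
ASV27	17	5	66	11	22	24	51	20	39	4	0	83	46	19	0	11	2	8
ASV28	3	2	4	5	1	6	0	1	3	3	1	1	6	1	9	1	1	1
ASV29	217	298	50	10	65	180	21	38	57	27	2	122	7	62	10	19	53	7
ASV30	8	36	94	21	60	79	84	72	23	6	10	35	169	39	7	51	76	30
ASV31	1	0	1	1	3	2	1	1	1	2	0	0	8	5	0	5	2	1
ASV32	79	47	4	7	5	4	5	106	15	14	9	103	1	5	0	5	40	3
ASV33	18	9	103	21	11	8	28	31	150	9	1	51	58	62	4	80	25	62
ASV34	57	148	10	0	3	50	21	9	9	3	1	40	15	14	0	4	38	1
ASV35	163	137	11	17	8	79	49	55	32	29	4	34	24	34	1	6	100	12
ASV36	12	9	55	11	9	332	49	75	101	24	8	134	101	64	2	69	35	35
ASV37	23	3	36	65	5	149	48	18	9	38	5	26	71	32	115	23	2	4
ASV38	1	34	11	1	21	4	9	2	0	5	3	1	6	30	15	54	35	47
ASV39	6	4	2	4	1	1	5	2	1	0	3	15	1	3	0	1	17	4
ASV40	13	53	2	112	83	29	78	29	125	53	71	6	5	36	39	6	4	12
ASV41	682	423	85	140	66	106	57	151	154	44	11	605	159	32	5	7	273	25
ASV42	205	211	95	85	720	386	314	78	70	259	114	64	97	82	203	394	306	814
ASV43	302	14	12	6	18	18	19	3	9	12	0	30	4	15	1	9	17	15
ASV44	16	4	19	22	14	12	25	3	11	13	2	1	35	8	59	23	5	1
ASV45	200	51	69	151	79	277	594	107	61	129	2	15	270	89	857	45	84	18
ASV46	96	15	144	42	142	324	195	442	393	77	20	910	135	370	21	122	150	65
ASV47	26	15	35	9	14	51	8	25	21	5	2	8	54	23	1	50	22	21
ASV48	43	48	4	88	54	90	23	17	8	32	18	9	7	25	19	55	13	32
ASV49	14	4	10	2	2	14	7	0	2	6	0	1	37	5	4	0	2	0
ASV50	8	22	28	133	22	53	164	11	4	30	16	20	177	3	100	14	30	40
ASV51	1	1	4	5	10	23	2	6	7	4	0	11	10	10	0	11	9	2
ASV52	21	27	5	31	6	8	29	33	13	8	7	52	0	3	0	3	67	6
ASV53	2	7	2	51	27	3	16	10	5	10	9	5	34	9	58	7	0	14
ASV54	2	0	5	1	7	39	34	21	8	0	2	11	22	14	1	34	15	7
ASV55	3	7	0	0	1	0	1	0	1	2	0	0	0	0	0	0	1	0
ASV56	4	1	2	8	0	14	5	4	1	14	0	0	14	6	23	4	3	1
ASV57	24	1	35	40	16	40	50	4	13	6	1	0	39	6	37	2	5	3
ASV58	11	27	8	1	2	23	4	15	5	2	2	46	12	8	2	3	34	17
ASV59	3	3	16	4	8	3	7	0	4	1	0	4	13	13	2	35	8	13
ASV60	7	9	8	16	8	32	18	14	39	29	5	8	72	15	81	115	37	9
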