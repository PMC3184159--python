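gene	snp	ww_case	ww_control	wv_case	wv_control	vv_case	vv_control	maf_case	maf_control	or	ci_low	ci_high	model	p	bootstrap
BMP2	rs235757	174	157	198	192	45	68	0.35	0.39	0.64	0.42	0.95	REC	0.029	96
INHA	rs7588807	107	82	216	241	94	94	0.48	0.51	0.70	0.50	0.98	DOM	0.035	64
INHBC	rs2228225	131	171	203	174	83	72	0.44	0.38	1.48	1.11	1.99	DOM	0.008	100
INHBC	rs4760259	165	199	199	171	53	47	0.37	0.32	1.39	1.06	1.84	DOM	0.019	95
SMAD1	rs11724777	160	155	200	177	57	85	0.38	0.42	0.63	0.43	0.91	REC	0.014	100
SMAD1	rs6537355	340	319	69	93	8	4	0.10	0.12	0.69	0.49	0.98	DOM	0.036	11
SMAD2	rs1792689	328	301	87	105	2	11	0.11	0.15	0.69	0.50	0.95	DOM	0.024	85
SMAD2	rs1792658	256	228	138	166	19	19	0.21	0.25	0.75	0.56	0.99	DOM	0.043	55
SMAD3	rs10152307	243	206	140	179	34	32	0.25	0.29	0.72	0.54	0.95	DOM	0.019	100
SMAD3	rs4776892	269	244	123	155	25	18	0.21	0.23	0.73	0.55	0.98	DOM	0.035	28
SMAD3	rs7183244	192	160	167	186	58	71	0.34	0.39	0.74	0.56	0.98	DOM	0.035	88
SMAD6	rs4147407	313	343	100	69	4	5	0.13	0.09	1.60	1.14	2.24	DOM	0.007	100
SMAD6	rs4075546	185	152	185	199	47	66	0.33	0.40	0.77	0.63	0.94	ADD	0.0099	100
SMAD6	rs16953584	258	235	144	150	15	31	0.21	0.25	0.45	0.24	0.87	REC	0.016	95
SMAD6	rs2053424	139	166	212	182	66	68	0.41	0.38	1.43	1.07	1.92	DOM	0.017	51
SMAD6	rs5014202	278	251	125	145	14	21	0.18	0.22	0.78	0.61	0.99	ADD	0.040	67
SMAD6	rs4776318	140	116	198	201	79	100	0.43	0.48	0.82	0.68	1.00	ADD	0.047	83
SMAD7	rs17186485	370	346	47	67	0	4	0.06	0.09	0.63	0.42	0.93	DOM	0.021	94
SMAD7	rs3736242	229	259	168	137	18	21	0.25	0.21	1.37	1.03	1.81	DOM	0.029	51
SMAD7	rs7238442	124	120	206	193	84	104	0.45	0.48	0.70	0.50	0.99	REC	0.041	2
SMAD9	rs648206	118	127	195	210	104	80	0.48	0.44	1.45	1.04	2.02	REC	0.029	61
SMAD9	rs576434	141	115	191	213	85	89	0.43	0.47	0.74	0.55	0.99	DOM	0.046	61
TGFB1	rs8179181	269	236	119	158	24	21	0.20	0.24	0.72	0.54	0.96	DOM	0.025	100
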