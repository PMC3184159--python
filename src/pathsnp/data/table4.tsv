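block	haplotype	control_n	control_pct	case_n	case_pct	or	ci_low	ci_high	p
1	H0:W_W_V	318	48.04	344	51.96	1.0
1	H1:W_W_W	119	50.00	119	50.00	0.85	0.63	1.16	0.303
1	H2:W_V_W	192	55.33	155	44.67	0.72	0.55	0.95	0.018
1	H3:V_V_W	205	48.69	216	51.31	0.95	0.74	1.21	0.654
2	H0:W_W	622	48.56	659	51.44	1.0
2	H1:V_W	79	58.96	55	41.04	0.64	0.44	0.92	0.016
2	H2:V_V	133	52.78	119	47.22	0.85	0.65	1.12	0.247
3	H0:V_W	356	48.44	379	51.56	1.0
3	H1:W_W	211	53.96	180	46.04	0.80	0.62	1.03	0.081
3	H2:W_V	265	49.07	275	50.93	0.99	0.79	1.24	0.942
4	H0:W_W_W	430	50.18	427	49.82	1.0
4	H1:W_V_W	116	45.85	137	54.15	1.19	0.89	1.57	0.236
4	H2:V_V_W	74	49.01	77	50.99	1.01	0.72	1.43	0.934
4	H3:V_V_V	206	52.02	190	47.98	0.96	0.75	1.22	0.741
5	H0:W_W_W	308	49.12	319	50.88	1.0
5	H1:W_W_V	120	54.55	100	45.45	0.77	0.56	1.07	0.117
5	H2:W_V_W	120	47.62	132	52.38	1.00	0.75	1.35	0.976
5	H3:V_W_V	282	50.54	276	49.46	0.94	0.74	1.18	0.575
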