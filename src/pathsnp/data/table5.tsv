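node	label	control_n	control_pct	case_n	case_pct	or	ci_low	ci_high	p	boot_low	boot_high
1	Low risk	27	81.82	6	18.18	1.0
2	Medium low risk	115	57.79	84	42.21	3.25	1.28	8.24	0.013	1.38	11.32
3	Medium high risk	246	46.24	286	53.76	5.08	2.05	12.56	0.0004	2.21	16.76
4	High risk	29	41.43	41	58.57	6.33	2.32	17.28	0.0003	2.42	22.14
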