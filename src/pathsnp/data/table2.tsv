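category	control_n	case_n	or	ci_low	ci_high	p	boot_low	boot_high
2-4	31	9	1.0
5-7	174	122	2.45	1.12	5.33	0.02424	1.13	6.20
8-10	177	220	4.42	2.04	9.57	0.00017	2.07	11.18
11-13	32	61	6.75	2.83	16.12	0.0000168	2.78	18.47
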