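group	n	n_caucasian	age_mean	age_sd
case	417	339	60.73	10.36
control	417	349	60.30	10.71
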