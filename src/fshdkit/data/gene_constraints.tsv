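gene	z_missense	z_lof	benign_cutoff_freq
SMCHD1	3.63	8.55	0.00012
LRIF1	0.24	2.77	0.0001
DNMT3B	1.5	5.26	0.00012
CTCF	4.44	5.079	0.0001
EZH2	4.68	5.808	0.0001
DNMT1	4.99	8.20	0.0001
DNMT3A	3.45	1.521	0.00062
SUV39H1	3.49	4.333	0.0001
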