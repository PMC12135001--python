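cultivar	n	male_as_male	female_as_female	male_as_female	female_as_male	failed
Pu	22	10	12	0	0	0
Cr	30	15	14	0	1	0
Ch	8	4	4	0	0	0
D1	33	15	18	0	0	0
Ti	18	12	6	0	0	0
Ma	12	6	6	0	0	0
Ks	29	15	14	0	0	0
D8	29	15	14	0	0	0
D2	1	0	1	0	0	0
Ca	1	0	1	0	0	0
No	1	0	1	0	0	0
Fi	8	4	4	0	0	0
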