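group	unit	total_loci
Group 1	CAG	4960
Group 1	CCG	1511
Group 1	CGG	1602
Group 1	CTG	3518
Group 1	GCC	1882
Group 2	CAG	423
Group 2	CCG	196
Group 2	CGG	204
Group 2	CTG	211
Group 2	GCC	223
Group 3	CAG	121
Group 3	CCG	54
Group 3	CGG	40
Group 3	CTG	67
Group 3	GCC	57
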