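cross_id	V	LEM	count
t5-02	white	lemon	116
t5-02	white	green	78
t5-02	green	lemon	8
t5-02	green	green	64
t5-03	white	lemon	147
t5-03	white	green	99
t5-03	green	lemon	18
t5-03	green	green	83
t5-04	white	lemon	293
t5-04	white	green	14
t5-04	green	lemon	6
t5-04	green	green	295
t5-05	white	lemon	310
t5-05	white	green	11
t5-05	green	lemon	14
t5-05	green	green	324
t5-17	white	lemon	64
t5-17	white	green	5
t5-17	green	lemon	3
t5-17	green	green	73
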