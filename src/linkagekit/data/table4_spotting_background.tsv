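cross_id	S	LEM	count
t4-02	spotted	lemon	70
t4-02	spotted	green	130
t4-02	non-spotted	lemon	54
t4-02	non-spotted	green	12
t4-03	spotted	lemon	103
t4-03	spotted	green	172
t4-03	non-spotted	lemon	62
t4-03	non-spotted	green	10
t4-04	spotted	lemon	6
t4-04	spotted	green	294
t4-04	non-spotted	lemon	293
t4-04	non-spotted	green	15
t4-05	spotted	lemon	17
t4-05	spotted	green	323
t4-05	non-spotted	lemon	307
t4-05	non-spotted	green	12
t4-15	spotted	lemon	2
t4-15	spotted	green	38
t4-15	non-spotted	lemon	50
t4-15	non-spotted	green	1
t4-16	spotted	lemon	4
t4-16	spotted	green	83
t4-16	non-spotted	lemon	96
t4-16	non-spotted	green	8
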