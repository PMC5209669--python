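cross_id	RLF	LEM	count
t6-02	rugose	lemon	41
t6-02	rugose	green	94
t6-02	non-rugose	lemon	40
t6-02	non-rugose	green	15
t6-03	rugose	lemon	69
t6-03	rugose	green	106
t6-03	non-rugose	lemon	43
t6-03	non-rugose	green	17
t6-04	rugose	lemon	29
t6-04	rugose	green	272
t6-04	non-rugose	lemon	270
t6-04	non-rugose	green	37
t6-05	rugose	lemon	62
t6-05	rugose	green	295
t6-05	non-rugose	lemon	262
t6-05	non-rugose	green	40
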