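cross_id	LEM	count
t2-01	lemon	248
t2-01	green	76
t2-02	lemon	124
t2-02	green	142
t2-03	lemon	165
t2-03	green	182
t2-04	lemon	299
t2-04	green	309
t2-05	lemon	324
t2-05	green	335
t2-06	lemon	13
t2-06	green	16
t2-07	lemon	104
t2-07	green	85
t2-08	lemon	52
t2-08	green	39
t2-09	lemon	0
t2-09	green	236
t2-10	lemon	0
t2-10	green	108
t2-11	lemon	0
t2-11	green	187
t2-12	lemon	0
t2-12	green	193
t2-13	lemon	0
t2-13	green	124
t2-14	lemon	0
t2-14	green	29
t2-15	lemon	0
t2-15	green	28
t2-16	lemon	0
t2-16	green	213
t2-17	lemon	68
t2-17	green	77
t2-18	lemon	37
t2-18	green	29
t2-19	lemon	49
t2-19	green	14
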