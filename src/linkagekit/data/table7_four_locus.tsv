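cross_id	V	S	LEM	RLF	count
t7-01	green	spotted	green	rugose	563
t7-01	white	non-spotted	lemon	non-rugose	528
t7-01	white	non-spotted	lemon	rugose	71
t7-01	green	spotted	green	non-rugose	56
t7-01	white	spotted	lemon	rugose	4
t7-01	green	non-spotted	green	non-rugose	1
t7-01	green	spotted	lemon	rugose	19
t7-01	white	non-spotted	green	non-rugose	21
t7-01	white	spotted	lemon	non-rugose	0
t7-01	green	non-spotted	green	rugose	0
t7-01	green	non-spotted	lemon	non-rugose	1
t7-01	white	spotted	green	rugose	0
t7-01	green	spotted	lemon	non-rugose	3
t7-01	white	non-spotted	green	rugose	4
t7-01	green	non-spotted	lemon	rugose	0
t7-01	white	spotted	green	non-rugose	0
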