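cross_id	F	LEM	count
t3-02	fancy	lemon	64
t3-02	fancy	green	79
t3-02	lance	lemon	60
t3-02	lance	green	63
t3-03	fancy	lemon	89
t3-03	fancy	green	87
t3-03	lance	lemon	76
t3-03	lance	green	95
t3-18	fancy	lemon	21
t3-18	fancy	green	18
t3-18	lance	lemon	16
t3-18	lance	green	11
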