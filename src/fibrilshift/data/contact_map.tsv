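site_i	carbon_i	site_j	carbon_j	min_mixing_ms	relative_amplitude
a	1	c	1	200	1.0
a	4	f	4	400	1.0
a	4	g	4	400	1.0
a	4	j	4	400	1.0
b	4	f	4	400	1.0
b	4	g	4	400	1.0
b	4	j	4	400	1.0
c	4	f	4	400	0.4
c	4	g	4	400	0.4
c	4	j	4	400	0.4
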