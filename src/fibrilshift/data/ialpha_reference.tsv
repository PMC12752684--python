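site	c1	c2	c3	c4	c5	c6	domain	role	major
ia1	105.3	72.1	74.9	89.4	71.5	65.4	1	unassigned	true
ia2	104.9	71.5	74.1	90.3	70.9	65.3	1	unassigned	true
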