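site	c1	c2	c3	c4	c5	c6	domain	role	major
origin	106.1	71.8	74.5	89.2	72.8	65.2	1	core-origin	true
center	104.3	71.8	75.4	88.4	71.3	66.0	1	core-center	true
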