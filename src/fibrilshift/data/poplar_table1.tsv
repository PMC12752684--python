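site	c1	c2	c3	c4	c5	c6	domain	role	major
a	106.1	71.8	74.5	89.2	72.8	65.2	1	core-origin	true
b	105.4	72.6	75.8	89.3	72.7	65.4	1	unassigned	true
c	104.3	71.8	75.4	88.4	71.3	66.0	1	core-center	true
d	105.2	72.5	74.9	87.1	72.5	64.7	1	unassigned	false
e	105.0		74.7	89.8	71.1	65.3	1	unassigned	false
f	105.0	72.4	75.1	84.4	75.6	62.7	2	surface	true
g	104.7	72.0	74.8	84.6	75.2	62.2	2	surface	true
j	105.7	71.4	74.6	83.5	74.0	62.4	2	surface	true
k	104.5	71.9	74.9	83.9	74.3	61.8	2	unassigned	false
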