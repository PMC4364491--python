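# lineage	positions	residues	weight
U	7	Y	1
U	59	Y	1
U	84	Y,R	1
U	143	T	1
U	146	K	1
U	147	W	1
U	159	Y	1
U	171	Y	1
Z1	7	Y	1
Z1	59	Y	1
Z1	84	Y,R	1
Z1	143	T	1
Z1	146	K	1
Z1	147	W	1
Z1	159	Y	1
Z1	171	F	2
P	36	C	1
P	67	C	1
S	6-9	C	1
S	48	C	1
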