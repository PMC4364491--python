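# HLA-A2 mature position	accepted residues
7	Y
59	Y
84	Y,R
143	T
146	K
147	W
159	Y
171	Y
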