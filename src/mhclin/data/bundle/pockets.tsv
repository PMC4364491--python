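# HLA-A2 mature position	primary pocket
7	A
9	B
24	B
25	B
33	B
34	B
45	B
59	A
60	B
63	A
66	A
67	B
70	B
73	C
74	C
77	F
80	F
81	F
84	F
95	F
97	C
99	A
114	D
116	F
123	F
124	F
133	F
143	F
146	F
147	E
152	E
155	D
156	D
159	A
160	D
163	A
171	A
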