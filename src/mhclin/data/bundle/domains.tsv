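# domain	start	end (mature numbering, 1-based closed)
alpha1	1	90
alpha2	91	182
alpha3	183	274
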