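symbol	logFC	p_value
GPNMB	0.263	2.9E-06
TIMP1	-0.69	6.32E-17
LGALS3	0.17	8.30E-06
NPPB		0.32
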