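subject	side	mode	measured	reference
E	left	lesioned	94.88	429.25
E	right	lesioned	149.25	392.13
E	total	lesioned	244.13	821.38
M	left	lesioned	190.50	516.63
M	right	lesioned	372.88	503.13
M	total	lesioned	563.38	1019.75
N	left	lesioned	109.38	607.63
N	right	lesioned	70.13	553.75
N	total	lesioned	179.50	1161.38
S	left	lesioned	398.37	484.12
S	right	lesioned	308.12	495.12
S	total	lesioned	706.49	979.24
T	left	lesioned	364.00	442.88
T	right	lesioned	326.63	494.50
T	total	lesioned	690.63	937.38
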