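	BomTac	MrkTac	ShiJcl	ShiLtDvs	ShiLt
BomTac	0	79	80	86	85
MrkTac	79	0	81	74	73
ShiJcl	80	81	0	89	88
ShiLtDvs	86	74	89	0	37
ShiLt	85	73	88	37	0
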