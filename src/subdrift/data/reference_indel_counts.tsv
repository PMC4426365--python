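	BomTac	MrkTac	ShiJcl	ShiLtDvs	ShiLt
BomTac	0	22	29	22	26
MrkTac	22	0	25	26	30
ShiJcl	29	25	0	31	27
ShiLtDvs	22	26	31	0	18
ShiLt	26	30	27	18	0
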