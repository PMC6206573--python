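A	pp	E
A	pp	D
B	pp	E
B	pp	C
F	pp	G
F	pp	H
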