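method	modules	module_size	q	bhi
FG	8	2~509	0.1992	0.1766
MCODE	21	3~110	0.0242	0.4465
NeMo	290	4~89	0.0523	0.3643
MOfinder	257	4~22	0.3263	0.4611
IPCA	819	5~45	0.3403	0.421
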