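FAM1	A1	0	0	0	2	ngs
FAM1	A2	0	0	0	2	ngs
FAM1	A3	0	0	0	2	ngs
FAM1	A4	0	0	0	2	ngs
FAM1	U1	0	0	0	1	ngs
FAM1	U2	0	0	0	1	ngs
FAM1	U3	0	0	0	1	ngs
FAM1	U4	0	0	0	1	ngs
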