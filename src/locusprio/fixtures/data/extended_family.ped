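FAM1	EA01	0	0	0	2	extended
FAM1	EA02	0	0	0	2	extended
FAM1	EA03	0	0	0	2	extended
FAM1	EA04	0	0	0	2	extended
FAM1	EA05	0	0	0	2	extended
FAM1	EA06	0	0	0	2	extended
FAM1	EA07	0	0	0	2	extended
FAM1	EU01	0	0	0	1	extended
FAM1	EU02	0	0	0	1	extended
FAM1	EU03	0	0	0	1	extended
FAM1	EU04	0	0	0	1	extended
FAM1	EU05	0	0	0	1	extended
FAM1	EU06	0	0	0	1	extended
FAM1	EU07	0	0	0	1	extended
FAM1	EU08	0	0	0	1	extended
FAM1	EU09	0	0	0	1	extended
FAM1	EU10	0	0	0	1	extended
FAM1	EU11	0	0	0	1	extended
FAM1	EU12	0	0	0	1	extended
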