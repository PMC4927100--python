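sample	chrom	start	end	kind
A1	chr20	18033000	18033317	loss
A2	chr20	18033000	18033317	loss
A3	chr20	18033000	18033317	loss
A4	chr20	18033000	18033317	loss
A1	chr20	20500000	20500120	gain
U2	chr20	21000000	21413065	loss
A2	chr20	22000000	22010000	gain
A3	chr20	23100000	23100500	loss
U1	chr20	24000000	24005000	gain
A1	chr20	25000000	25000999	loss
A2	chr20	25000000	25000999	loss
A3	chr20	25000000	25000999	loss
A1	chr20	30000000	30001000	gain
A2	chr20	30000000	30001000	gain
A3	chr20	30000000	30001000	gain
A4	chr20	30000000	30001000	gain
U3	chr20	30000000	30001000	gain
U4	chr20	30500000	30500200	loss
A4	chr20	31000000	31000150	gain
U1	chr20	17500000	17500250	loss
U2	chr20	18200000	18200300	gain
A2	chr20	19000000	19000120	loss
A3	chr20	26000000	26000200	gain
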