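chrom	pos	ref	alt	rsid	maf
chr20	18022362	C	A	rs6111803	0.0403
chr20	18031455	A	T	rs6045164	0.0409
chr20	20835294	C	T	rs540742459	0.0016
chr20	21206234	A	G	rs759099707	NA
chr20	23028063	A	G	rs11696919	0.0192
chr20	23564038	G	A	rs186922449	0.005
chr20	25636109	G	A	rs145320819	0.0032
chr20	26175891	C	T	rs145247716	0.0014
chr20	29638726	G	C	rs567212483	0.0268
chr20	30616835	G	A	rs6089151	0.0188
chr20	18469617	G	GTGTGTGTGTA	rs35822681	NA
chr20	20034644	G	GTT	rs772688050	NA
chr20	20034661	T	TG	rs761128007	NA
chr20	20034665	T	TTGTTTTTG	rs776918983	NA
chr20	20035056	T	TACACACAC	rs759860912	NA
chr20	30434096	G	GACGACAC	rs144761785	NA
chr20	30660366	TTAAAAAAAA	T	rs3838038	NA
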