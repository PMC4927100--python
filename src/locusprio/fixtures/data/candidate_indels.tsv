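chrom	pos	ref	alt	rsid	maf	gene	category	label	refseq_id	transcript_id
chr20	18469617	G	GTGTGTGTGTA	rs35822681		RBBP9	utr3	c.*318	NM_006606	ENST00000337227
chr20	20034644	G	GTT	rs772688050		CRNKL1	intronic	intron 1	NM_016652	ENST00000377340
chr20	20034644	G	GTT	rs772688050		C20orf26	promoter	c.-244	NM_015585	ENST00000245957
chr20	20034653	G	GT	-		CRNKL1	intronic	intron 1	NM_016652	ENST00000377340
chr20	20034653	G	GT	-		C20orf26	promoter	c.-253	NM_015585	ENST00000245957
chr20	20034661	T	TG	rs761128007		CRNKL1	intronic	intron 1	NM_016652	ENST00000377340
chr20	20034661	T	TG	rs761128007		C20orf26	promoter	c.-261	NM_015585	ENST00000245957
chr20	20034665	T	TTGTTTTTG	rs776918983		CRNKL1	intronic	intron 1	NM_016652	ENST00000377340
chr20	20034665	T	TTGTTTTTG	rs776918983		C20orf26	promoter	c.-265	NM_015585	ENST00000245957
chr20	20035056	T	TACACACAC	rs759860912		CRNKL1	intronic	intron 1	NM_016652	ENST00000377340
chr20	20035056	T	TACACACAC	rs759860912		C20orf26	promoter	c.-656	NM_015585	ENST00000245957
chr20	30434096	G	GACGACAC	rs144761785		FOXS1	promoter	c.-296	NM_004118	ENST00000375978
chr20	30461617	GAAGGAAGGAAGA	G	-		TTLL9	intronic	intron 1	NM_001008409	ENST00000535842
chr20	30461617	GAAGGAAGGAAGA	G	-		DUSP15	promoter	c.-417	NM_080611	ENST00000339738
chr20	30660366	TTAAAAAAAA	T	rs3838038		HCK	intronic	intron 2	NM_002110	ENST00000520553
chr20	30660366	TTAAAAAAAA	T	rs3838038		HCK	ncRNA	exon 2	-	ENST00000470092
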