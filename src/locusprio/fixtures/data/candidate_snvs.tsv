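chrom	pos	ref	alt	rsid	maf	gene	category	exon	label	refseq_id	transcript_id	biotype
chr20	18022362	C	A	rs6111803	0.0403	OVOL2	synonymous	3	c.327C>A	NM_021220	ENST00000278780	protein-coding
chr20	18031455	A	T	rs6045164	0.0409	OVOL2	promoter	-	n.-72A>T	-	ENST00000462208	processed transcript
chr20	18038585	T	C	-		OVOL2	promoter	-	c.-307T>C	NM_021220	ENST00000278780	protein-coding
chr20	20835294	C	T	rs540742459	0.0016	MRPS11P1	promoter	-	n.-9C>T	-	ENST00000437558	processed pseudogene
chr20	21206234	A	G	rs759099707		KIZ	promoter	-	n.-544A>G	-	ENST00000441136	processed transcript
chr20	23028063	A	G	rs11696919	0.0192	THBD	utr3	1	c.*351A>G	NM_000361	ENST00000377103	protein-coding
chr20	23564038	G	A	rs186922449	0.005	RP11-218C14.2	promoter	-	n.-244G>A	-	ENST00000437612	unprocessed pseudogene
chr20	25636109	G	A	rs145320819	0.0032	RN7SL594P	promoter	-	n.-592G>A	-	ENST00000470590	miscRNA
chr20	26045831	C	T	-		FAM182A	promoter	-	n.-452C>T	-	ENST00000439881	lincRNA
chr20	26175891	C	T	rs145247716	0.0014	MIR663A	promoter	-	n.-493C>T	-	ENST00000596717	lincRNA
chr20	29638726	G	C	rs567212483	0.0268	MLLT10P1	promoter	-	n.-666G>C	NR_045115	ENST00000418346	processed pseudogene
chr20	30616835	G	A	rs6089151	0.0188	CCM2L	synonymous	7	c.1107G>A	NM_080625	ENST00000262659	protein-coding
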