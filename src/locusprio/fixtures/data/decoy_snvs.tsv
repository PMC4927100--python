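chrom	pos	ref	alt	rsid	maf
chr20	20031100	A	G	-	
chr20	20031300	A	G	-	
chr20	20031500	A	G	-	
chr20	20031700	A	G	-	
chr20	20031900	A	G	-	
chr20	20032100	A	G	-	
chr20	20032300	A	G	-	
chr20	20032500	A	G	-	
chr20	20032700	A	G	-	
chr20	20032900	A	G	-	
chr20	18025000	A	G	-	
chr20	18026000	A	G	-	
chr20	21206800	A	G	-	
chr20	21206850	A	G	-	
chr20	21206900	A	G	-	
chr20	21206950	A	G	-	
chr20	21207000	A	G	-	
chr20	21207050	A	G	-	
chr20	26046300	A	G	-	
chr20	26046350	A	G	-	
chr20	26046400	A	G	-	
chr20	26046450	A	G	-	
chr20	26046500	A	G	-	
chr20	26046550	A	G	-	
chr20	19200000	A	G	-	
chr20	19201000	A	G	-	
chr20	19202000	A	G	-	
chr20	19203000	A	G	-	
chr20	19204000	A	G	-	
chr20	19205000	A	G	-	
chr20	24500000	A	G	-	
chr20	24501000	A	G	-	
chr20	24502000	A	G	-	
chr20	24503000	A	G	-	
chr20	24504000	A	G	-	
chr20	24505000	A	G	-	
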