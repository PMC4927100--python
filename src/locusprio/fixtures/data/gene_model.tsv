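gene	transcript	refseq	biotype	chrom	strand	exons	cds_start	cds_end	promoter_window
OVOL2	ENST00000278780	NM_021220	protein-coding	chr20	-	18022100-18022487;18030000-18030099;18038100-18038278	18022152	18038200	1000
OVOL2	ENST00000462208	-	processed transcript	chr20	-	18030500-18031383	-	-	1000
MRPS11P1	ENST00000437558	-	processed pseudogene	chr20	+	20835303-20835800	-	-	1000
KIZ	ENST00000441136	-	processed transcript	chr20	+	21206778-21207500	-	-	1000
THBD	ENST00000377103	NM_000361	protein-coding	chr20	-	23027500-23030500	23028414	23030300	1000
RP11-218C14.2	ENST00000437612	-	unprocessed pseudogene	chr20	+	23564282-23565000	-	-	1000
RN7SL594P	ENST00000470590	-	miscRNA	chr20	-	25635200-25635517	-	-	1000
FAM182A	ENST00000439881	-	lincRNA	chr20	+	26046283-26047000	-	-	1000
MIR663A	ENST00000596717	-	lincRNA	chr20	-	26175100-26175398	-	-	1000
MLLT10P1	ENST00000418346	NR_045115	processed pseudogene	chr20	+	29639392-29640000	-	-	1000
CCM2L	ENST00000262659	NM_080625	protein-coding	chr20	+	30610000-30610199;30611000-30611149;30612000-30612149;30613000-30613149;30614000-30614149;30615000-30615149;30616629-30617100	30610050	30616928	1000
RBBP9	ENST00000337227	NM_006606	protein-coding	chr20	+	18468000-18470000	18468100	18469299	1000
CRNKL1	ENST00000377340	NM_016652	protein-coding	chr20	-	20030000-20031000;20036000-20036500	20030201	20036399	1000
C20orf26	ENST00000245957	NM_015585	protein-coding	chr20	-	20033000-20034400	20033200	20034300	1000
FOXS1	ENST00000375978	NM_004118	protein-coding	chr20	-	30433000-30433800	30433101	30433700	1000
TTLL9	ENST00000535842	NM_001008409	protein-coding	chr20	+	30460000-30460500;30462500-30463000	30460100	30462800	1000
DUSP15	ENST00000339738	NM_080611	protein-coding	chr20	-	30460300-30461200	30460400	30461101	1000
HCK	ENST00000520553	NM_002110	protein-coding	chr20	+	30655000-30655200;30658000-30658300;30662000-30662400	30655100	30662299	1000
HCK	ENST00000470092	-	processed transcript	chr20	+	30658000-30658300;30659000-30661000	-	-	1000
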