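sample	chrom	pos	ref	alt	genotype
EA01	chr20	18022362	C	A	het
EA02	chr20	18022362	C	A	het
EA03	chr20	18022362	C	A	het
EA04	chr20	18022362	C	A	het
EA05	chr20	18022362	C	A	het
EA06	chr20	18022362	C	A	het
EA07	chr20	18022362	C	A	het
EU01	chr20	18022362	C	A	hom_ref
EU02	chr20	18022362	C	A	hom_ref
EU03	chr20	18022362	C	A	hom_ref
EU04	chr20	18022362	C	A	hom_ref
EU05	chr20	18022362	C	A	hom_ref
EU06	chr20	18022362	C	A	hom_ref
EU07	chr20	18022362	C	A	hom_ref
EU08	chr20	18022362	C	A	hom_ref
EU09	chr20	18022362	C	A	hom_ref
EU10	chr20	18022362	C	A	hom_ref
EU11	chr20	18022362	C	A	hom_ref
EU12	chr20	18022362	C	A	hom_ref
EA01	chr20	18038585	T	C	het
EA02	chr20	18038585	T	C	het
EA03	chr20	18038585	T	C	het
EA04	chr20	18038585	T	C	het
EA05	chr20	18038585	T	C	het
EA06	chr20	18038585	T	C	het
EA07	chr20	18038585	T	C	het
EU01	chr20	18038585	T	C	hom_ref
EU02	chr20	18038585	T	C	hom_ref
EU03	chr20	18038585	T	C	hom_ref
EU04	chr20	18038585	T	C	hom_ref
EU05	chr20	18038585	T	C	hom_ref
EU06	chr20	18038585	T	C	hom_ref
EU07	chr20	18038585	T	C	hom_ref
EU08	chr20	18038585	T	C	hom_ref
EU09	chr20	18038585	T	C	hom_ref
EU10	chr20	18038585	T	C	hom_ref
EU11	chr20	18038585	T	C	hom_ref
EU12	chr20	18038585	T	C	hom_ref
EA01	chr20	23028063	A	G	het
EA02	chr20	23028063	A	G	het
EA03	chr20	23028063	A	G	het
EA04	chr20	23028063	A	G	het
EA05	chr20	23028063	A	G	het
EA06	chr20	23028063	A	G	het
EA07	chr20	23028063	A	G	het
EU01	chr20	23028063	A	G	hom_ref
EU02	chr20	23028063	A	G	hom_ref
EU03	chr20	23028063	A	G	hom_ref
EU04	chr20	23028063	A	G	hom_ref
EU05	chr20	23028063	A	G	hom_ref
EU06	chr20	23028063	A	G	hom_ref
EU07	chr20	23028063	A	G	hom_ref
EU08	chr20	23028063	A	G	hom_ref
EU09	chr20	23028063	A	G	hom_ref
EU10	chr20	23028063	A	G	hom_ref
EU11	chr20	23028063	A	G	hom_ref
EU12	chr20	23028063	A	G	hom_ref
EA01	chr20	30616835	G	A	het
EA02	chr20	30616835	G	A	het
EA03	chr20	30616835	G	A	het
EA04	chr20	30616835	G	A	het
EA05	chr20	30616835	G	A	het
EA06	chr20	30616835	G	A	het
EA07	chr20	30616835	G	A	het
EU01	chr20	30616835	G	A	hom_ref
EU02	chr20	30616835	G	A	hom_ref
EU03	chr20	30616835	G	A	hom_ref
EU04	chr20	30616835	G	A	hom_ref
EU05	chr20	30616835	G	A	het
EU06	chr20	30616835	G	A	hom_ref
EU07	chr20	30616835	G	A	hom_ref
EU08	chr20	30616835	G	A	hom_ref
EU09	chr20	30616835	G	A	hom_ref
EU10	chr20	30616835	G	A	hom_ref
EU11	chr20	30616835	G	A	hom_ref
EU12	chr20	30616835	G	A	hom_ref
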