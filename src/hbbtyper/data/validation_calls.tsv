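# 15-sample validation cohort: sequencing calls as printed, with the
# standard-test (Sanger/IEF) diagnosis used as the concordance reference.
sample_id	sample_type	hgvs_c	depth	vaf	printed_zygosity	standard_diagnosis
FH	WB	c.20A>T	1645	0.46	het	Sickle cell heterozygote
G213707J	WB	c.2T>C	49715	0.56	het	Beta+ thal heterozygote
G213708H	WB	c.2T>C	43165	0.44	het	Beta+ thal heterozygote
G213709R	WB	c.2T>C	80434	0.77	hom	Beta+ thal intermedia
G213711L	WB	c.2T>C	127405	0.41	het	Beta+ thal heterozygote
Z	WB	c.20A>T	4744	0.50	het	Sickle cell heterozygote
TMK-1196	DBS	c.20A>T	91193	0.81	hom	Sickle cell disease
TMK-1258	DBS	c.20A>T	118680	0.45	het	Sickle cell heterozygote
TMK-1259	DBS	c.20A>T	46389	0.55	het	Sickle cell heterozygote
TMK-1260	DBS	c.20A>T	32431	0.55	het	Sickle cell heterozygote
TMK-1267	DBS	c.20A>T	38726	0.55	het	Sickle cell heterozygote
TMK-1276	DBS	c.20A>T	41793	0.53	het	Sickle cell heterozygote
TMK-1287	DBS	c.20A>T	86884	0.95	hom	Sickle cell disease
TMK-1345	DBS	c.20A>T	17534	0.85	hom	Sickle cell disease
TMK-1536	DBS	c.20A>T	33070	0.93	hom	Sickle cell disease
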