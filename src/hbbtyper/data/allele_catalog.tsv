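hgvs_c	protein_name	allele_class	note
c.20A>T	Glu7Val	beta_S	HbS; sickle allele
c.2T>C	Met1Thr	beta_plus	start-loss; reported clinically as beta-plus
c.92+1G>A		beta_plus	IVS1-1G>A splice donor
c.92+1G>T		beta_plus	IVS1-1G>T splice donor
c.114G>A	Trp38X	beta_zero	stop-gain, exon 2
c.118C>T	Gln40X	beta_zero	stop-gain, exon 2
c.67G>T	Glu23X	beta_zero	stop-gain
c.9T>C	His3His	benign	same-sense polymorphism
c.180G>A	Lys60Lys	benign	same-sense polymorphism
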