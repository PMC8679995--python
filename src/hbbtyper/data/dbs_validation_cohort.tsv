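# Nine newborn DBS genotypes for simulation: the sickle allele in five
# heterozygotes and four homozygotes, plus the benign His3His polymorphism
# (one het, eight hom). Haplotype columns are comma-separated HGVS lists.
sample_id	hap1	hap2
TMK-1196	c.20A>T,c.9T>C	c.20A>T,c.9T>C
TMK-1258	c.20A>T	c.9T>C
TMK-1259	c.20A>T,c.9T>C	c.9T>C
TMK-1260	c.20A>T,c.9T>C	c.9T>C
TMK-1267	c.20A>T,c.9T>C	c.9T>C
TMK-1276	c.20A>T,c.9T>C	c.9T>C
TMK-1287	c.20A>T,c.9T>C	c.20A>T,c.9T>C
TMK-1345	c.20A>T,c.9T>C	c.20A>T,c.9T>C
TMK-1536	c.20A>T,c.9T>C	c.20A>T,c.9T>C
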