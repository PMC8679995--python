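# The three compound-heterozygous discovery samples, simulated with the
# second lesion in trans with the sickle allele.
sample_id	hap1	hap2
S144	c.20A>T	c.92+1G>A
S245	c.20A>T	c.114G>A
S462	c.20A>T	c.118C>T
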