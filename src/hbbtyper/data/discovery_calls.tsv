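# Discovery cohort non-synonymous calls as printed (one row per call).
# Sample 750's second variant was printed with depth but no VAF.
sample_id	hgvs_c	depth	vaf	printed_zygosity	final_diagnosis
S144	c.92+1G>A	5849	0.44	het	Beta+ Thal, Sickle cell heterozygote
S144	c.20A>T	5845	0.48	het	Beta+ Thal, Sickle cell heterozygote
S245	c.114G>A	5817	0.40	het	Beta+ Thal, Sickle cell heterozygote
S245	c.20A>T	6023	0.48	het	Beta+ Thal, Sickle cell heterozygote
S462	c.118C>T	5934	0.47	het	Beta+ Thal, Sickle cell heterozygote
S462	c.20A>T	5969	0.46	het	Beta+ Thal, Sickle cell heterozygote
S647	c.20A>T	11078	0.49	het	Sickle cell heterozygote
S693	c.20A>T	5967	0.51	het	Sickle cell heterozygote
S926	c.20A>T	6700	0.99	hom	Sickle cell disease
S040	c.20A>T	4847	0.45	het	Sickle cell, Beta+ Thal heterozygote
S040	c.67G>T	4787	0.44	het	Sickle cell, Beta+ Thal heterozygote
S1077	c.20A>T	3741	0.46	het	Sickle cell, Beta+ Thal heterozygote
S1077	c.67G>T	3688	0.44	het	Sickle cell, Beta+ Thal heterozygote
S1221	c.20A>T	3287	0.45	het	Sickle cell, Beta+ Thal heterozygote
S1221	c.67G>T	3258	0.45	het	Sickle cell, Beta+ Thal heterozygote
S832	c.20A>T	3806	0.48	het	Sickle cell heterozygote
S750	c.20A>T	3619	0.47	het	Sickle cell, Beta+ Thal heterozygote
S750	c.92+1G>T	2169		het	Sickle cell, Beta+ Thal heterozygote
S1181	c.20A>T	3111	0.46	het	Sickle cell heterozygote
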