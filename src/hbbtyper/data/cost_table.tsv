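name	reactions_per_item	cost_per_reaction	units_per_sample	sharing
QiAmp DNA blood mini kit	250	1.86	1	per_sample
Enrichment Step 1	200	0.72	1	per_sample
Enrichment Step 2	1000	0.93	2	per_sample
Enrichment Step 3	50	9.24	1	per_library
PCR barcoding kit	960	1.42	1	per_sample
Ligation sequencing kit	6	80.00	1	per_library
SpotON flowcell	192	1.98	1	per_flowcell
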