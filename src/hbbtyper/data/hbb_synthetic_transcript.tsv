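# feature	start	end   (0-based half-open, locus coordinates)
exon	100	192
exon	322	545
exon	845	974
CDS	100	974
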