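sample_id	barcode
BC01	AACCGAAGGTTTCTCT
BC02	CCAGGTAGGTAAAGCG
BC03	CTGAGACCGGGGTGGT
BC04	AGACCAGCGAAACGGC
BC05	GGTCTGCCTATACTAA
BC06	AGCAAAGCTGATGGGG
BC07	TGTTTACATCCTAATA
BC08	CTCAGAGGAATTAGTT
BC09	CAACTATCCGTCGCAT
BC10	CAATTATAGAGACCGG
BC11	ACTCGGCGTGCGAGAC
BC12	ATTGCTATTTCTAATC
BC13	CCTCTCCAGTTCCGCA
BC14	ACCTTGGCGCTTATTT
BC15	GCAACCCCACATTCTT
BC16	TCGGGGTCCGGAACCA
BC17	AAAGCCATGCACCAAT
BC18	GCTGTAGTTGGCATCA
BC19	GGCGGAGCGTATCCCA
BC20	ACACCCCCTTGATAAT
BC21	ATCCAGGTTGAGAGGT
BC22	CCCGTGTAAGGGCTGC
BC23	TCTGCTCCTTTGGAAC
BC24	GGGCCACGTGCGGTCC
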