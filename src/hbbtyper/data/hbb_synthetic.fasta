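>HBB_synthetic synthetic beta-globin-like locus (sense strand)
CCCCCTCCTGAATCCCATTAACTAGATGTCACGAGTGGGAAAGGTGGTCTAACCCCGATC
GGGCGTCCGGGACGACGGGCGCAGTTCGCTTTGTTGTACTATGTCTCATCTACATCCCGA
GCCGATCACGGGCTTTACTTGCTGCTTACATACGATTACGTGCTTGGAGGGGGATCAGGG
GCCTGTGTCCCTGTGCTTTATATTGCAGTATCTCTCACTGGGCTAGATAGATTCGGGGCC
GATAACCGCACGTCCAGAGTCCACAAAGGGAACCGGTCTGGTGAAAGATATCAAGCTAAA
AAATGTGATCAACCCCTTCTAGAGGAATAACGGAAGAAACTTGGAGACAGTTGGAGGGTG
AAACTTCCTTTATAAAAAAGGTGATGGTCCCGCAACGACGAGTCACAAAGATACCCATGC
GCATCAATGCGAACGGAGACAATGTAAGCCTGGGCGTGTGGGCGGGACCCGGACCGCAAA
AGGATATTGCCGAATTAATTCTTGCCCCGTGCGCTATTCAACAAAACCTATGTCGCGGGG
CAGACGTTTTAATGCAACGTATTGGATTAAAGCTCGCTGGACGTTATGATCAGTCATTGT
CAGCTTCCGACGCAGCGGGCGAAGTACGGTTTGTTCAACAATAGTCGCGCAAGCGGCACG
CAGACGCATGTCGGTAAAAGATTCCCACGCTTAGCCTCACTGACCTCCTGTCGGTTGGGT
GTGTGAGAGGAACAATCACGCTCACATAGATTAAAGGTAGTCTAGAGTATACGCCCCCAC
TTCCTACCCATAAATAGGCGAAACCAGAAATCCGCTTACAGCAACGCATGTGTAGGCTTC
CCTAGGAGCTCCGTCCAGAGGAGGAGCTTATCATGGATTGCATTCAATATCCCGATAGAC
ATAAAATCATAAGTGTACGGAACCTCCAACTTTGTCCTAAGGACCCCCGCTCCGGTCTAC
AACTAGCGTTCTAAGGTTATAACTAGGGACACTATATACCCACTTCCCTGGACTCCCATC
GCCATCGGGCCAAATTTGGTGTCGCCAGAAGGCACATGTTTCAATTTGAAACGC
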