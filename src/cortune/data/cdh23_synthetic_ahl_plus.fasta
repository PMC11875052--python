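>cdh23_synthetic_ahl_plus synthetic stand-in for the Cdh23 exon-9 Ahl+ allele (BsrI site ablated at the SNP; not the real locus)
CTTATGATTTTATAGACTCCTCCCGTAGACCTCGCTAGCTGGAATCACAGGGATGTACAGTCTCCCACTA
ATGTAGGGGTTGATTCATAGCGCCGGGACTCCTAGGCAAGCAGTAGCGTCGTGCTGTTGGGCCTCCTTGC
CACCTTGTCGATGGTTAGTGAGCTTAAGTATTCTAAGGACCGCCGAGTATAGGCCGAGTGGCTCAGACAA
CTCGAGTATACGCCTTTGCTTTTTGAGCGCCCTTGGACCGGCCAGGGACAGGCGAGTGCTATCACCCACA
TAGACACTCGACAAGCTTACTTGGCCCGAGCTCTCCATCGCTATCCTAGTTTGATCTGCCGCAATACGCT
CGAACACTACCTTGCAATCTAATACAGCAGCGGTATTTAGGGGGGATAACTGAGAGCCTGGCATTAATGG
TCATAGCAACCACAGCTCGTCATGGATGCTGTTCGTTAAGCTAAACGCTGTCGAAGGCGGGAAATAGTCG
CTTCTCGTCTCCACTACAACCAAATGTGAGCGCATTATACTAGCCCTCTCAAAACCCAACCATACGTCAT
GTCGGACCGGGTTACCAGACCAGAACATAGTAGTCATGGGACGTTTTACGAGCTCAATTGAACAGATTAC
TACCATGGATGCTACGTCTAGCATTATGTTATGGAGTCAAACGACGAAGCGGATAACTGATAGTCATAGA
TTGCAAGCCAAGCGTCATGGGAAGAGGACCTTAGGAGGGGTCTGAAATCTCTCGACGAGCATAGCTCTCT
CTTCCTCCAATTCCAGCCTCAACCAGGCGCATGGGCAAGGGTACGAGTGCCCGGAAAGTATAGTTGACGT
ATGATGCAACGAGCTCAGTTCAGGGAGGGCTCGCGGTCCACGTACGTATAAAGAATAGACTAAATAGCGC
CACAGTGCAATCGGCGGGTTTCGCGAGTCGCAGTTCATTGGTAGCAGACACAAACTAATCACGACTCCCT
ACGGATGTGACAAAAAATTGAGAACATTCTCGCTGGCTCCAACCGTGCGTGAGGATATCTGGCAACAAAA
TAGATCATGGTCCACCCCAGATACACCGGCTTGCTATTTACGCGTGAAAGATAGTGAATCGACGGACGGA
AATAGTGTCACGCTTAATAGTAAACCGTCCGGTCTTGGATGCGACTACGCAGGAGATCGTAAAAGCTT
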