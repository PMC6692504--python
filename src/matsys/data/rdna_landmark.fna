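>rDNA_landmark|landmark|toy
ATCGAATGTAATAATAAAGAGTTCTCACAGATACATGATTGGGGAGGGATCTAAGAGTAC
GTGCAAACTTCCCTGATTGACTTATTGTCTTCGCTCGAGTCAGTGACATTTTTCGTCGGG
CTATAGTCGCCAATGTTCAACGTGGCCCGAGCTCTATTGCCTTTTCGGAGGAGCTCTCAT
CTCAATAGATTACGAGAGACAACAGATTTCCGGTGTAAGAGGGTTTCCTTCGACACGCAA
ATCGGGATCTTAACGAGGAAGTATACTATTACTATTCAGAACTGGAGGAGTTAGGTCATG
TCAACACTACCCGGGCACAGGAGCTTCAACTTACGTATTTATCTGTACCACATTGTCTTC
AAGTTTCTCTAATTTGTGGATAGTTAGCTAATGTTTTAAGTTTGTCAAACATCATACACG
CGGTTGTTTAATTAACTGTTCTGATTTCCTCACTAGTGTATAAAGTACAGCCAAATATGC
ACTCTCGATGATCATGAGCTTCATCTTAATTGTAAGAGGTATAGAAACACGCTTTTACAC
TCTCTGCTCGAAAGAGGGAGTAGACATCGGCATAAGGCTTTTATTGACCATTCGACGCCA
ATCAAGTTTCAGCCTCGAGCCGTTAAAGCTTAAATTGAACAGTGTCGAGTATTGTATCCG
TATGCCTGAGTGGATCTAAAAAGCCCCAGGTCCCCAAAAGTCAATTTATAGAGAACTCTT
TTTACAAAACGAAGCCTTAGGAACTCCAGGCACCGTGTATTATTCATCTTATGCACTCGG
TGAATCCCCAGACACAGGGATAAAAGTAAATGATAGCAATTGTTTTAATTTGATTTAAGA
AACAAGATTCGTCAACCAGGTTGGAGGCCGTTTCCCGACTTTTGTTGAACGTGCCAACGT
TTTCGCTCTTTGCCCTGAATGTCCAACAGTTCAGGTCATTTTAGGTCCCATGATAATCGT
TGATTCCCCATCCCAAGAGGTAGTGAAGAGAGCCAATAATTTCTTTGCATACTCTCCCGA
ATCTGAAGGTTGTCGGCTGTGTTTAATTTAGAATTGGTCGATGATATCAAGGTGCCGTGC
ATTCTATCGAGATTAGAATGGTGTAGTTGCGCCCCGCTCTCAGCCTCTTCTACGTGGAAA
AGGGTGTTTAATAGCGCGTTTAGACGTTTTCTATCTAAATGGTTTGAAGCTATCTCGTGA
AGAACTTTTCCCGTGGAATTTTAGTGCGTACATTCGGTGACCCGGAAAGATCTTAACTAA
CTGATGAAATTGCGCGATTATGTCTTTGCATCCTATTACTTTGAGAGGCGGGTGCTTCTT
TAATACTAACAATTGCTTCTTTACCTAGACGGGTCATCCTCTAGAAGGCTTTATTCATTG
CATGCACTAATCAATAATACAGTCGACTGTGCACTTCAGACCGCGAGTTCGCTTTCGAAA
CTAACACCTGTTCCTAACATTGGAGGGTTATTCCCTATATCCATGTCCGACCATTTCATC
TGCTCATCGACTCTACCGCCGGTACTGCGTGCTATAATCATAAACTGGATAGTACGATAG
TCGATCGCAAACTTGTCCTATTACTTCTTTTGACTTCCAGTATTCAATTTAAATTTTATG
GCATGAAGACAAGGCCAAGGATGATGACAATCCTACATAATAGAACGGTTTACAATTGGT
GCTCCAAGTATCAGAAATCCCTACCACGGACGCGTCGGATCTAACAATAATCATATTGCT
CTCAATTATGGAAGATGTAGCCTCTGTATTGCGCCCTCCTTGGCTCCTGGGTTTTGTGTA
TTAGCGAGTTTTGAAGTGTCGGTAAGTGATCACGAAGAAAAGAAATGGTAATTTACACCT
GTAAAATATTAATTCAAGAAAACGTTACCTAACGACAACAATGTGGCTTGCTATATCCTT
GTAGAAATATGCTCAAGGAGCGCCTTATGTGTTTATTCAATGTGGACAGCTACTGAATAA
TATGAGGGTGCTCGGCTCAT
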