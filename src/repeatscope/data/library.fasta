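>telomere_TTTAGGG_x10_synthetic
TTTAGGGTTTAGGGTTTAGGGTTTAGGGTTTAGGGTTTAGGGTTTAGGGTTTAGGGTTTA
GGGTTTAGGG
>satellite_140bp_consensus_synthetic
CTATAAATAGTTAATCAGACACGGCTGATCTAATTTTTGATTGTGACTCTCGTGTGCCAA
AAGATTGAGTGCGTGATAACGTTTAGTGTGGGCACATCTAACAACGTGGGGATGATTCGA
TCTCCTGCTAGTCTTTCAGT
>rDNA_unit_3kb_standin_synthetic
ATTTCCTTAACCTATGTGTTGGCATTAGTATACTCCCCCTTCTGTTTAATGAGCCCTGTA
CGGTAATGCATGTTTAAGATTCACAGTTAATTGATATAAGAACTCCGGTACAATTAAGTT
GTCGTAAAGCTGAACCGATATTTGTTCATACCAATAAATTATGCGTATCAAGATGGTACT
TGAATTTAAAATGTCGACCTTTATCGTTGGCTCGAATTACGAGATAGACGTAGAATCGGC
GCCCTTCGAAGAACTACTTTTTCTCAAGCGGCATCTAACAGCGTCAACCAAGGAAATATA
TGGAAAAGGACGGAACAGATGCAAACAGACGTGTAGAAAATAATTATCAGCACTTCTAAA
CCCACGTTGCGCAATATATCATGCCTCTCCAGTCCGTGGCCTAGTATGTTAACGTAGAAT
AGGGCATAGTGGGACTAAATAGTTAAGTCCGAGATGTTAACATTTTTACTGGTAGGAGAC
GTGTTACCTCAAGTTAACAAGTTTATGTTGTCAGTGTTGCAACACTTAGTCTAGATAAAA
CCGATTCGGGAAAGGCGGCCGGTCAAATCACGCGATATATAATAGCGCGGAGTGTTGCGG
TTTGTGGTCCAAAGGGTAAAGTTCAAAGAGCACTCAAAGATCCGCAGTAAAAATGTACAA
TCAGACCAGGATTTGCCAAGGGGTGAGTTCGTAACGCTCGCCCCGGTGCTGAAGTAGACT
AGCGAAACCGGCAACGGGCTATTAATGAGTTCTTAACCCCGCACGTCTGCGAAAATTTTG
CCTATGGAAATGAGGCTTTTAAGTATTTCCGAAGGCATGGTTGGATGCGCTGCTTCTCCT
TTACACATGCGCCCTTTCTTGTAGAAAATATCAAAAGTAAGTCAATAGTACACTTTGATA
CCATGCCAAATTACAAGAGTCCGGTTGCTATTTGGCCCACTGCGCGTGGCGGGTGCAACG
TTGCGCAACGCCCTGTGGGCCGTCCTATCGCACCTGCTTTTTAAGGAAATTACGTTATTT
CTTTCGAATAATACAGTTAGACGAGTGAATAAGTTGGGCTTAACATCTTTAAAGCTACTG
GTTGTGTGATATTATAGTTACTGCCATTTAGTGAACCCATAAGGTGTCTTAAAGGATTAG
CTTCCATCCATCTTTACAATCTGCTGTATCGGCTGATTTCGTACCGTTATGCACAATTAG
AATGGACCTAAGCGCGTTCACCTAAGTACGATGGTGGGTTTGGCTAATAACAAGCAACAC
TACCTACTTAGAACACCCTGTGAATGATGACTTTCGAATATGGGCCATGAAGCATTTAGA
TATTGATCGTGGAACTTCAGGGCAAACAGTCGTTAGTCTGTCCGCAAATTCTTCAACATT
TAAGCTCGGGGCTTTTAAACTTATAGACACGACGCTGAAGGAAGCCTAGATATCCCCAAG
AACAATCCTTCATAGAACGCTTTTGCATAGTGCTCATAAACAATAAGAGCTGAGATCTTT
CTGCCTCTACTAGAATGAATCTACGCTCAACGACATACGTACTTCCCTATTGTTCTTGGT
GGATGAACTTAGGACATCGCACTGCTGACTTGGATTTTAGCGAGGGGCCAGCCCATGCGG
GGTCGTGAAATCTGTGCCTTACAGGTAAGGAGAGGGCACACACGTATTGTGCATATTTTT
GTACGGCGGCAGAATCATCTTAACTGGTGAGCGTCGCCAGACTTGTGCGATCAAGGTGTC
CGGATACTTGCTTATAGCGCTGGGCGGTAGTACACTGTCACTTCGTGTTCGGTTCGTACC
ATCTCGTTTCATTAGCAATATACTAAGGCTATAGATAAACGCCGTGTATTTAATAAGAGA
TATGCATAACCGCCGATGAAGAATATCTATATTTTTGAGTGTTGAACATGCCCTCCGTTC
TCGATGCTAATTACTATAGAGATGATGGTCTACATTTAATACCGCAACAAATCATTAGTA
ACCAGTCAGTATCAGTCAAAGTATGAATCGAACAGAATCCTCTTAGTGCATCAAGCAGAA
TGTTCTTTTAGTCTCTGGGATGAGGATCAGAAAGATTTGATCTATGACAATGACGTAATC
TCTCAAACCTTTGATCATAAGCTGTTGATTATTTAGGGGAATACTTAACCTTATTCGGCA
CAGCTTCATGCTATATACGCCTATTGACTATCAACTGGGTGAGTCCAGGACTGAGATGTG
CTTGAACAGGGCCAGACGATGGAAGGTTTATCACCGTTCAACCGCGGCGTGTCTGAGATG
TAATGAAACATGGATACTATCCTTATACGTATCATGAGTAAGAAAGGACCAGAGACCACG
TTCCGAGCGCTCTTTAAGTGTAGGATCGATGCCTTCTCGGTTATTATCTCAGAATGTTTA
ATGTCCGTAATAGTATGAGTACTAAGTCGCGCGACCCAATACTCGGTAAAATCCAGTATA
ATTAAGTGGACAAATCAATTTAGGGGCTATCGAAGCCTATTCTTTATCATACTGCGCTGA
CACTCATTCATGAGACTACCTCCTCAAAGACAACGCGTTTCATTCGTCTAAATCTACGAA
AAGGTTTATCGGCTTCAGGCTCAATATGATATTTTAGGCACTCGTTTAAAATACACCTTA
ACTAGTAGTTACTTGACTAATAGAGTGTGAGGCTTAAAACTGATATTTCTCATTCCGCCG
CCACACTGTCGCTCAGATTGCTTACTGCGGAACTAGCCCAAATGGCTCGGGAAGGTTACT
GCGAACCAGTAGACTTATGTTATCGAAAATAAGTCTCATGTTGTTTTACTCCTTAAGGCA
ACCATTACCTAGGACCCACTGCAAAGTTAATCTCAGAGTCCTAGAAGGATCAAATAAATG
ACTACCAGATACCCGAAGTCTGACAGGGTCTCTGCATGGCGGTGCCAGAGGCCGATTCCA
ACGCCCATCCACAGCACGTTTTTATTAAGTTATTTCATAAAGCGTCCTTCATCGATTCCC
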