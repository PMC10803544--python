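>FCGR1_ref synthetic reference transcript (ORF only)
ATGGTGCATTTCTGGTGGGCTGCCCAGTGGCTGGCTGCCGGTGCTGTGGCTGCCGCCCTGCTGGCAGTTC
TGGAAAGCGAACATCCAGCCATCGATAAACATATCGCCAAACATTACATCATCCAAATCCAGGTTGCCGC
CCTGGTGTTCGCTGCCAGCTGGAGCGAACTGCTGTGGTTCAGCCTGAGCTGGTGGGAAACCGGTCATGTG
CATTTCCTGGCTGCTTTCGTTGTGACCTGGCTGCTGACCAGGGATTACGTGAGCGATAAAGCCGTGGAAC
TGAGCCAGCATTACTACTGGGTGAAAAAAGTGGTGGCTGCTAAACATGCCGATGCCGCTTTCCAGGTGAC
CTGGAGCGTGGCCCTGCTGTACTACTTCCTGTACTTCGATGCTAAAAAAGGTATCGGTGTGCTGAAAAAA
GATGGTGATTGGCATCAGAGCTACTACGGTGATTACCTTGAAGGTAAAGCTAAACATTTCTACGCTAAAA
CCAAAGCTGAAAAAGCTGCTGTGCATTGGTGGCAGATCTTCGAAACCTTCGCTTGGAAAATCCATGTGAA
AGATGTGGGTGTGGCCGTGCATCATAAACTGTTCTACTTCCCGACCCAGACCCAGAGCGAATACCAGGAT
AGCCTGGGTTTCCTGACCAAAGAAAGCAAAGTGTACGAATACGCCGGTACCATCGCTGATGAAGCTCAGC
TGGTGTGGACCCAGCATGATGATGCCAGCCATTTCTACAGCACCGATATCGTGGTGTGGGTGAGCAGCCA
TAGCATCCTGCATCAGGCTTTCTACCAGGAAGATGATTGGCAGCATATCGTGCAGGCTCATCAGACCGAA
GGTTACGATTGGCTGGAAGTGTTCAAATTCCAGGTGAGCCATTACGCTTACGCTGCCAAAAAAAGCTTCG
ATGTGATCGGTGCCTTCGGTATCGCCGTGGGTACCGTGACCACCGATTGGACCCAGCTGCAGGCTCTGCA
GCAGGAACTGGCTTACCAGAGCGATAAAGATTACTACCTGTTCGATGCTGAAGATGTGTTCGTGTGGGTG
GGTAGCGGTGTGCAGGCCGCCTGGAAAGAACTGGGTAAAATCACCGAATACAAAATCCTGAAACTGTAA
>FCGR2A_ref synthetic reference transcript (ORF only)
ATGGATATCAAAGTGCAGGCTTGGAGCGATTTCACCATCATCGGTAGCAAAGCCGGTCATGCCCATGCTG
CCGCCCAGTACCATGCCATCCTGATCCATGCCGATGCTTACCCGGTGCAGTTCATCGGTGGTGTGGCTGG
TGCTGTGGGTCATGATATCACCGTGGCTTACTTCCATAGCTGTCATGAAACCTGGAGCTACAGCTGGGTG
GAAACCAAAGTGGCTAGCGCCGCCGGTTACGCTTTCGATGAAGGTAGCCTGGCCGCCATGTACAAACATG
AAACCGGTGCCAAATGGGAAATCAAAAAAATCGATGTGGCCTACGGTGATAAAAGCTTCTACTACGCCAA
ATGGATCGAACAGTACAGCTGGAAAGCCCAGTTCTTCTGGGTGGTGACCTGGGTGGGTCATGAAGCCAAA
GATAGCAAAGAAGCCGGTTTCGAAAGCGATCAGGAACAGGGTGCCGGTTACGGTCTGAAAACCCAGAACG
AATCTCATAAAAATCAGGCCTACTACATCCAGCAAGAAACCCACGCTTGGGAAAGCTACTACTACGGTGG
TCATGCCAGCAGCTACATCCAGTTCCTGTGGACCTTCGCCGTGGAACAGGATGAAGCCATCCATCATACC
ACCGTGCTGGCCAAAGAAAAAGCTTGGTGGGCTGCTTTCAGCCATCTGCTGTTCCAGTACATCGCCTGGG
CCGGTGCTCTGAGCTACCAGGAACATAGCCTGAAATACTTCAGCACCGCCGCCGGTGAAGATTACCTGAT
CACCGATGATAAAAGCTACGTGTGGTACGATGAATTCGAACTGTTCGCCGCTAGCGAAGAACATAAATGG
GAAGATAAAGTGGGCATCGATACCGTGAGCTACTTCACCAAAGGTATCGCTGAACGTCATTTCCAGATGG
TGCATCAGCTGACCGCCTTCTAA
>FCGR2B_ref synthetic reference transcript (ORF only)
ATGGGTCATAGCGTGACCGGTCAGCAGGGTAGCAGCGATGCTGTGCAGTACCATGATAAACAGTGGTACC
AGGTGCAGACCCATGCCAGCGAACATTGGGTGGCTACCTGGGCCCTGACCCTGAGCGGTGGTACCATCTT
CTTCCATCAGATCCATGGTATCCATTGGAGCCAGAAAGTGGTGCTGGCTTACCAGATCGCTCATACCGTG
CAGAGCGGTGCTAGCTTCAAATACAGCTACGATTACGCTCTGTGGTACGTGATCCAGTGGATCTGGCATA
GCCAGAAAGATGCCGCTGAAAGCGGTACCTGGTGGATCCTGGATTACCAGGGTGATTGGTTCAAAGGTCT
GTTCCAGAGCAAAACCGCTAAAAGCCTGGATTGGCAGGGTGTGGTGCTGGATCTCGCTGTGCTGAGCGCT
AAAGTGACCCTGATCGTGCTGCTGGTGTACGATTGGGAAGAAGATTGGATCGGTTACCTGCAGGCTGCCA
CTACCCATGATCTGACCATATCTACCAGCGATTGGGCTGCTAATACCAACTACGGTCTGCATCAAGCTGG
TAGCATCGCCGCCGCCCTGACCTTCGATACCGCTACCAAACAGCAGGAAATCTTCTACGTGGTGCCTGAT
GATAGCGCCACCGCCGTGAGCGAAACCCTGGATCAGGGTATCCAGGAAGCCTGGGAATTCAGCAAAGCTG
ATGATCATCAGTACAAACATTTCAGCGATTACGCCCATGGTACCTACTTCCATAGCGTGGCTGCTGAAAA
ACTGATCCATGAAGCTCAGCAGCTGGATAAAGATTGGGAAATCTTCGTGCATAGCTTCGTGGTGAGCAAA
GCTGATAGCGCTGGTAAATTCAAAGATCAGGTGGATCTGGAAGGTTACGCCGTGAAATTCCTGCAGCTGA
GCATCCATGAACATGAAAGCATCATCCAGCTGATCCTGATCTACATCTAA
>FCGR3_ref synthetic reference transcript (ORF only)
ATGTGGGCTATCAAACATAGCGGTAGCATCGAAGCTAAAGAAGTGACCATCTACTTCTGGGGTCATTTCG
AAGCTACCGCTGGTAAAAAAGAATTCTGGATCGTGCTGTACATCGTGGGTTTCCTGAGCAGCCAGGCCCA
TAGCACCGGTACCAGCATCTACCTGTGGGCCAAAGTGGCTATCGCTGAACAGGAACTGTTCATCGAAGCT
GAAGAATTCTACGGTTACCTGAAAGAAGATAAAAGCCTGACCCATTACGCCCATAAAACCATCAGCGTGA
CCGGTTTCGGTGAACAGCAGATCGTGTGGCAGGATCTGGTGATCAGCGAACTGTTCTACTACACCGATGC
CTACTGGGTGGCTAGCTGGAGCCTGTTCCAGACCGTGGTGGAAACCCAGTGGTGGGGTCAGCAGCAGGAT
GTGGTGTGGATCCTGTACGGTTGGAGCGAAGAAGTGCTGAGCGCCTACGAAACCGTGGTGTGGTTCGCTT
GGACCATCGCCATCGAAGAAATCGATAGCCAGCTGACGTGGCATCTGCAGAGCCAGATCTTCACCTACTT
CACCAAAATCGATTTCGCCGCCGAAGCTAGCGCTGCCGCTACCTTCCTGGATGGTGCTGTGTGGTGGGGT
GATATTGCCGTGCTGATCCTGGATGCTGATCTGGTGCTGGTGAAACTGGCTTGGCATATCGCTCTGAGCA
GCAAAGCCGATAAAGATAGCTTCGCTTACGATATCTCTAGCGCCGCTTTCTTCCAGACCGATACCGGTGT
GTACTGGGATCATGATGCCGAAGTGTGGGATAGCGTTCTGCATGGTAAAAGCGCCAGCGTGTACTGGGCT
TAA
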