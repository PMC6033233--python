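>contig0
CACAGGATATCTGCGGACAAAAATAGCAAGCACGGAGTAGTTAGGTATTAACAGCAGATTACCAGTTGAC
CAATCATGGTATGATAAGCTCAAGAGACGATACAGTCTGGGAAGATATTTTAACCTGTGCGGGCGTGCCA
AAATAGAGGTAATAAGCCCTGACGATATTACCACGGAGGGGCACCCGGAGGTTGAGCAGATTCATCCCCC
ATGAATGGGCCAATGTGAAGGACTTATACGCAAGTGAGTAATCTCCGCAAAGAGTGAAACTACCGATCAT
TAAAAAGGCTATAGCCGTACTTAAGGACTGTAAAAGTGTCATACTCTAACATCCCCAGCTACGATGTTGT
CCGATCCCTATAAACATAGAACGGTACATGATTATAAATCACAGGGGCGCTCTACACAAAAGCCCACGAT
CGCTCAACTGCTAATCAGGCTCAGAGAATCGGGCAGCATCAACGACATTGTACATGTGCGCAATCAGGTA
GGGTCTGGTGTACTCAGGTCCCAAAAGTGCGCGGAATTGATAGCCTCACGGTGGCGGATTTAAGATTACT
GTCCTCCCCGAGTCTCCAGCCCGGGGTAGACCTGGGCACTTTGGGAGTATCAAACTTGGGCCATATCCAC
TCTAGTATAAGAGCCTGTGAGACGTATAGGGTGGGACAGGCCCATCACACCTTTATTAACGTGTTCGGGC
ATACAGGTCGCAAAAGCCTACTAAGGTCCTAGTCACCAATCCCGTATCTGATGATGACGTTAGCGTCTTG
GACAGCGACGGTCGCTGACATGTCACTGGCCCTCATAGCGCTTAGCCCAGAGCCTCCCGTTGAGGTTTTA
TGAGCTGGTT
>contig1
GGTCCTTAATAGGGTTATTTGGCAGTAGTATTGCTCGCTTTAGCATGGACGTTACAAGTCTTCAACGGCA
ATAATTTCCTTTGTAACAGCGTAGGACCGTCAAAATGTCCTGTGCAACAAGTTCAGTACATCCAGATCCT
GGGCAAATTACGTAGATGAAAGCCGGAAGGACACTGCGGGATTAGAAGAGAGGTATAGGTGCAATCGTGC
GTAATTAGGTAGGACTGTTTAGTTTGAGTGTGATCCCTACAGCGATTACCAGTTGACCGCTCATGGTTAC
TGCGTAATTGGCTTTATCGAATACGCCGGCTTCTAGGTTGCTCCGTCCATGATATGACTCTAACGATCAC
CGACCGCATTTCAGTTGGATACGGATCTTTTTAGTCGGGCATAACAATGAAGCTTTCCAGACTCAGCCCA
GGCTCTTGTTGCTGACAGGTAGCTCTTCTAGAGTGATATGTAATCGAGTCGAGCCGAATACTGACGCCGC
ATTCTCTAATGTTTCCGCTCCGTTAGGTCCGAACTCATGCTTCCAGTAGGCGCGTATTGTCGGAACAATC
ACCATGATCGGTCAACTGGTAATCCTATATCGAAGGGAGATTCTGTTCTCGCCGCAAAGTGTCGAGGGGA
CACGGTAGCCTATCAGTATCTAGAGTTTTCAGGAAGGATTTACTGAATCTAAAGGCCAAAAGCGATTTAA
CCAGAACTTGTAGCTTAACGCCGGTGACCTTTGATTACCAGTTGACCGATCATGGGCGCTGAATATGAAT
AAATTCCGAAGGTCCGACGCGTCATGAAGCTATGCGCAGCGATTTGGTAAAGGATTCCCATTGGACCTTT
CTAGCCGCAA
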