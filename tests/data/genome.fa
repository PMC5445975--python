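>I
GACAGGTACAAGAAGGAGTATGCATCAATGTGGTCGTGTGGAACAAACGCCACTGGAGAC
TGGGTTAACCATTCGCTCCAGCGTCATGAAAGTCACTGTTAGGGCGACCTTCGATTCGGA
TGTGACATTTCATTACATTACGCTCAGGACTGCGAACGAAAGATTAAGAATGCTTAACCC
GGTACCTAACCCATCTGATTTTTACACACTCTCCTTGGACTGGGAGGTATAAGGAATAGG
CGGTAGACGCCTACTTAACTTTCATGGTGATCGTAAAGCGGAGCCTTACCATGCGGCAAT
TGTGAACTTTTAAATTCGATTTTTAGCTTTTCTATTATCCTAAACTTCGCTGTATATCAC
GCGGCGCGATGGGGCAGCCTGCCCCCACTGTGCGACCGGCCACTTAAGGCTTGAAAACTA
CGAGCAGATTACATGAATCTGTGTTGGGTGTGCCAGTGGCACCCGAAGGACGCACTGGTT
CACTTTCGGGAACACGCACAGACGAGACACACTCTTCAAGTCGTGTTAAAAGGAGTAGGA
TTAACGTCGAGGATTGATTCCCGCTTATGTGCGTCTGCCGCTTATACGCATAATCTGCAT
AGCTGGCTAAGCGCGCGCGCCAAAGTAACGTGCAAAAAGCTGGATCTGCCAATCTCAGAA
GCTATGTAGCCTTCGGGTAAGAAAACGCAGGCGTTGGTCGGTTAACGGCAGGTGCAACCC
ATTGTTGCATCGTAGGCACCGTCGCTTGCCCTCGTGGCACTGTAGTCGATGAAGGATTCA
TCGGCTTAGCTGTTCTCTGTCCGTCAGCGGCCAGGATAGGTCGTTCAGGTTCGCGCGACT
CGGTTTCCGTTAAGTTGCAGTCGTATCCAGGTAATGATACCCATTGACCGGCCTACCAGG
TCTGCGGGAGCTCTGCGGGGGTGTGCCGGACGAAGTGTTCTCTGCATATTGTTTCTAGCG
GGTTAAATGTAATTCCATCCATACGGTCGACACCTACCTTAGGTCCAATCGGGATAAGAT
AATCATATAACAGAATACAAGGGCTGAGTATTGCTACCGCTAAGACGGCTGCGAGTGTGA
CACCCACGCATATAAGTGGGCACGTTGTGCGAGAATCTGTTTTGGATTCAGCCATGCAGA
GACCCGTGAAAGGCGCCCTACCGCGACGACAACCAGACGGTTATAATTGGGCAACTGTTA
AGCCCAATAAACCACTCTGTGGGATCTTCTGGGTGAACCCAGCCATATTGGCGTTCTGCC
AAATCGGAACCGACCCCGTGAAGCGGTTCGACTGCGTCCACTGGCCGAATAGGGATATAT
GGACTACATTTACCGACCGCGCTCTCTTCCCGTTTACGTGATTCTCTACTACCAAGATCA
TTGTACTGAGCAACTGGGAGGCAACGACATGTGCGGCGATGGTGCCGTCATCGGTGCAGT
ATCGGTATCCAAATGTGCTACTTCACTGTCTCCTGTGAGTGCAGCGCGCATCTCTTAGCT
GTAGTAATCCGGGTCTGGCGAAGCCGCCCTCTCATCTCAGTCCAGTTGTGTGAAATAGCT
GGACTGGTTATGCGCTTGATCTAAAACGCTTTCGGACGGATAGGGTGTAAGGGTCGCGCT
CTGCAACCAGCGGTTACGCCCAACCGATACGCTCGCCATGTACACTGCGTCTGTCCGAGA
GTCTGATCTCTTAGGAACCCGGCGATGCCTGGCTCGTGTGGACTTTGGGAGGTAGATAAC
AGCTTTGAAACGGCATCCTGGGGAAGATCCAGCCTTCAGCTTTTCCGCCCCAGTGAGGAG
GGACGATAGTCTTCATCGTAGGGTTATATTCCTTTTAGATCTGCTTCAAACCAGTGTATT
TGAGAACACATTCGAGGAACCGTGCATCGAAAGGCGCGGAATTACGAGAGGGACGAAGAG
TCGCACTGCTGGACATTATACTTTGCTCTTCGGGGCAGGGAAACGGGTACCTGATCTTAA
AAGGAGCAATAGCTGCGGCCAGACATTTGCCTTGTCCACTCTCGTTGTGAAAGTTAGACG
GTATGGCTCTATTATCAGATGTCGCCGCATCTTCCGAACTGCACCTCGGCTTGCATAGCT
GGAATTGTCTAGAGCGGGCCAGAGCTATGTTAAAAGTCCCCGTAGTGTTACGAAACCTGT
AGAATTCAATTGATCTGTGCAAATCTCTATGGTACTCTTCTACTCCTCGGAGTGAAGGGC
AACCCAACGCACAGCCCCATTTGACACCACCCACAGGAACTCGTCCTTTACTACTTCGCG
ACTCAGGGGGTCGCCGTTCCGAGGTATCCGTGGTCTGGATGCGATGCTTCACGGGGCCTG
GCAACTATACCACCCGCCTATGGATAAAGTACAGCAGAGCGATTAATACCCTGGGGGCTG
TGCGAAACAGGCACAGGGTGCACCACAATTGCGCTCAATCCGACGTGAATTCTAGGTATT
CTCCTCTTATGCGGAAAAACCGCGCCTTGATTTTTATAGTTGCGCCCGTAGCTCTCATGG
CGCAGACACTCGGCCGAATCATCATAGAGATCGCCTACCGAGGACAAGAGTTCAACGACT
ATTATAGAGCGGACGTAATGCTCACAGGGTGTGCGGGCATTCACGGTTTATGCGTTTAAC
AATGGGCGAGGCCGATGCGTGAGGTAACCGCGGAGGATGTGAATCTTATCAGGACCCGCC
AGGAGATACCATTGTGCCCGCACGTATTTACCTCGAAGCGCGCTATTAACACTTTAGTGA
GACATGATTGGCTAAATAGCTACCTGGCCAATGAACCGTACCAAGTGATCAACGGCTACC
GACTAATTATCGGGCTAATCATTCACAGTCAGAAACTAGACCGACAATGGTTTTCGCTGC
ACATTATGTTTAGCTTATATTCTTAGTGTAGTGGATTCCCAAAGATAAGTTCAGTTTTTC
TCACAATTTGATGTTAGACGAGTTCTTAGTTAGTAGATATAGGTCCAACAACGTTCCGAC
>II
TGGAATCCTAACGGTAGGCATATAAAAGGGCCAAGTACCCGGAAACATCCCGAGATCCCC
ACATGACGTGGTTCGTCTCATGGTTGGATATTTACTCTGTCTTACCCCCTTGGCCAGTTT
GACGCCCCGACAGGATCAGTTATCCCGATATCTCCGAATGTTTGACGATTAATTACTGCT
GGAACGATGCATGGCCAGTTGGCCATTATGGACTCTGCCCCCGTCAGGTCGGCAATGTCG
TCATTTTGGGGGTCCCAGGAGAGTTGGTTTAAACTTAGCACGCTCCCTCTGTATGTCCAT
AACGTCCGTCGAGACTATCTAGGCTCAACACTAGGAGCACGATCCGGCTTCTCATTCAGA
GGACGATCGATGGAGCCGCAGGCGGCGATAGAAAAACGAGCACATCAGTTGAAGGACATC
CAAACTCGATATGACCGTATACTCCTTGTAGATACGTGACCAGTTATACACCGGTGGTGC
GGAGACGCTGTAGATTTACATAAGCACTCTCACGACGAAGGCGAGTCAACGGCGGATACT
TCGGAAAGGAGATCCTGACTTGTCGTACGATTCGTAGGACGTGCTTTCTTCACGGCGTGT
GAGCCGTGTGGCACCGGCGTCTTGAAGATACCTGCTATATGTGGATTCGTCTTCGACGTT
TTGGTGGTTCAGAAGCCGAGCCGAACATGGCGCTCAAAGCGAAACCATGTTTAGCTGGTG
CTTCGCTTCTCATAGTATGAAGTTCAGGTTGTGACCAATGGACCGCAGGGGTGGATATCA
TCCGCGACTGTAGTTGCTGGAAGGTCGTCCGGAATAATTTTTCGCAAGCCAGAGTCCGCG
GCCCAAAGCTAGTCCCGAGTTAGCTAAAGAGCGTGGTCTCATGCCGCGGTTGAGCATGTG
CCACACAATCCCATCGGTTCGAGCGTGCTGCTCCGGAAAGAACGAATGCCAATAAGAGAG
ACATGGAGGCACTTATGTTAGCGCCGACAATGCAACGATGACAGTTTGGCAGATTCGGTG
AACATCTCAGTGAAGGCCAGCTCCCGTCTCCGCCCGGTGGCGAACCGGGATAAATCAAAA
CTGGGGTTGCAGTCAGGAAAAAATTCCGGGAACTTCTCGATGCCAACTTTTTGGTGTTTC
CGAAAGTGACTGATAAGTATCCTCTGTCAGTAAAGAATGGGTGACGCTTTCTTCAGATCG
GCGATGCGAAGCGCGACGCCAGCTCAAGAACACCATATACTTGGTCGGCCCCTTGCGACA
GTGACGCTTAGGGTCCGAATCGGTAAACCCGCCTCGTCAAGGTGAAAATGACTACAGTCA
CGATAGTCCTGCCTGAGGGGGGCCGTCCCTCGCCGTTGCCTAAACCTATAGGCCATTTGC
GTCTACGGCGAAAGAACGGAACCCTTCTCTTATACATTTATATCGACTGTCGCCGATGCG
ATTAAGCACCCACGGCTGCTAGACTCCTTCAATTCAGCATCCCGAACGCTTGAACCCAGC
AATTAGGGCGCGGCGAGATATACAGTGGGCCGATACTATAGTCCGTCAACTTAGGAGAGA
GCAGCCGTAACCATCCCTCCTCGGGATTCTCCGTGGTCCATATGCGGTAACACGATACTG
GTATGGTGCGGAATCTCTTAGGATCCAGAGAAGCCGGACCAAGACAGTAAGCGAGGAATC
TAGCCCGACTGTCAATACTTAATTTTAGACAAGAGCCGAGAGGAACTGAGACCTGTATGA
CTACTGAGCTAAGCCACCGATGTGTTTAGCATGACTGGAAATTCGAAGTTCGGATTATTC
GTACTGTTCCCTTTCTAATGCGAAGCGCGGGCTCAAATACCGTTATTTCCCACAGCCGGG
GTTGCTATGCGGGGACCCTCCGAGATCGATTGACCAGGACCGTTGAACCGCTGTCCTTGG
ATAGCCTCGAAAGCCTGATAGCCAGAGGGTAAGATGTCTACAGGGGTACGTACCCACGCA
GCGGGGAGGTCGTTCGCGTCAGGGCAGGTAAGATTTCCGGAACTCGCAGCGGAACCGTTG
CGTGCTCGTCGCGAGTTCTCATGTGCGTTGCACCACTACATTTCACGATGGTATTTGAGC
GGATGGACAGGCGCTCACCCAACAGGACCAGCAAGCCACGAACAGGTGGCTGGGTTCATT
CCGGCAATGTCGGTTCACCCATGAATTCGTGCCGGTCCTGTCTGAGATGCGCGTATAATT
CCGATTTGAAAGCGAGCGTCTCTCAATCACCGAGTCTTAGCCCCGGCACTTATGAAAGCC
TAGCCTGCAGGCCAGGTAGCGCTGGACGAGTTTCATACGTAGTCACTCGCGCTTCATGGG
ACAATTGCAGTCACTAAAGACTCGCTTCAATACTTACGAGCGTAACCGTGCGCATATCGT
GATGTCTTCCAGCTGGGACGAGGTAAACACAAATGTTGGATAGTGTTGCCTGTCCTTCAA
TCCATCCCTGACATAGTGAAGCCTAGTGCGTGGTCCTTTGATTCGTCGCGTAGTACTGAA
CAGTGCAGGAAGGCAGCGTCTAATAATGCGTAGTAAGCTAGAAACTCAGTACTATCTTGC
TGATTTGCAACGGCTAATGTACAAAGTCTTGAGGCTGAACTGTCAAAGACTGATGCATGT
CAGAGCCCTTAGTATCATGGCAGCTCAGTCACCTATCCAGGTAAGAATCACTGTGGATTA
TCTGTCGGACGTGAGATACTAGCTTCAGAGTACGACCGTGACTTCTCCGTATCACCTGTT
ATGATGTACGCAGAGATAACTGTAGACCGCACCGAGGGCGTTTTATCATCTACGCTGGCT
GACCGCATATGCCGCGGTCCATACCTTACCATGCTTGGAAACACAGACCCGACTCCACCA
GTCGCCTTGAGTCGGTAGCCTCAAGGATCAGCGAGACGTTCATCCCCTTAGCTTCTTCTA
GAACTTATTACTCGGTAACGATTCGCAACTTCGTCCGAACTAGGGTGCGAGGTAACTAAC
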