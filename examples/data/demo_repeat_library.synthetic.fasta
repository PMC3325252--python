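>Gypsy-demo1#Retroelements/LTR/Ty3-Gypsy-DIRS1
CTATTGTTCCAGCAGCGACAGCATGCAAGGCATCACGGTTGAAGCGCGGAAGAAAGAGACGACCAGGTGA
TTATAGGGACTGACGGAGGGAATGTGTTTAATGGGACGGAATCAATCCCCGGGCATAGTGCGCATATATG
TCGCTAACACGAGACCTCAACTAAAGTGGCAATAGAAATCCTGTACCTCCAAGGAGCCCTGAGATCTCTC
TCTATCGGTTGATGCCAAGCTAGAAGGGTCGCAGAACTTGTAAACGTACTGTAAAATACTCGTTGGCCAG
GAGAACAAAGAATCACCTCGCATAGACTACACTTGCCACTCTATGACACACGTAACGCATTGGAAAAGAA
GAAGAGTTACTGCAAAATCATGCTGTATCGAATGGCTAAACCCTAGCGGTTCTGTTGAACATATTGATTA
AGTAACACAGTCGCATGCCTTCACTGCTAACGCTGGTAAAATACCCCTGGGGACGCTCTTGATTTCCTAT
GCTTATATACCGCTCAGAGTGCACAACCAATATTATGAACGAATGTAGAGGCACTAAGTTAACTAAAGAT
CGTCGTTTAACAATGTACGTACGAAACTTTACCAGAAGGGACATAGGCAATCTGGGTGAATGGATTCACT
AATTACACTACCGGACACGCTACACACGCTTGCAGTCACCGATGTATGACGCTACGTATCCCCTCGATCT
CAGTAATAAAATAAAAAGCATAAGGAGATTCAATGGATACCCTAACTACTAACATAATTGTAACCATACC
ACGGAAACACCACTGTGGCAAGGGTTGTATATTATCCGCGTAACACGACGTCGCGCGAGCGTCCGCTCGT
CGCAAGCAACGAAGGTAAGTAACCTATTCGGCATTAACTTTAAACCGTAACTAATTAGCTGTAGACAGTG
TAAATATCTGATTTTGGTGACCGCCATAGTCTTTCATCTTAGAAATAACCTCGTTTATGTCACATATCTG
CAACTGACAGACCCTTCCGAAGTTTCCCGCGAATCTCACGGCATGCCACCATTGAGAAGAAGTTCTGAAC
ATGTGGCAACAAGTTGCTGATATCTGTCAACTGCCTCGACCCGTTGCAGATCCACAATGACAAGGACTGG
GCCTTCATCAGTACTCTATTACAAGATCGGTCAGGATTTCGTAGAGGTGGCAAGAGACTATGTACCTACG
ATCTGAACGCAGCCTTTACCACTAAGGTCCGAAGTTCGGTTCTCGCATCGAATGCTCAGTGAAGGATATA
TATGCCATCGACAGATCATCGAACAGGCTTCTGTACATAGGGCTTTTCGACGACTCCACAAGCATCAGTA
CATTTTTTACATTCTACTCTGCGATCTATTAGGATGATTAAGGCGGTATTATCTTTCCCGCTTTTGCGTG
>Copia-demo1#Retroelements/LTR/Ty1-Copia
TAGTTGGATCATGAACATGCAACCAATATTACGGTCGCTTCAGGGTTGTGCCGTAACCAGATCTGTGCAT
GGTGGACGGGAACAAGCTCAGCTTCTTCATGGATATCCGGCGTTACCACTCTTCTTTAACGACGAGTCTG
ACCAATTGCCGCTCTAGATACGACTCCAACCCTGTCCATGATGAAGGTAGGCTCCGAAAGACTACTGACA
TAAACTGTCAGGGAACCTCAATGTTTGGAGTCGAACGACAGCCTGCCGAGGTCCGGTGCTACGAGATTCA
AGTGTGCATAGGGTACTATGGCGTTGTCGTGCGGAGAAGGGCCTTTAGGGTGCTCTATCATATGGGGTAT
TATAGAACCAGTGAGTGTCTTAGTACTAGACATGACAAACGCAAATCCAGCTCACTTGCGCCAATAAATT
AATCTGTTACAGAGCTCCACATTGTTAACAGTAGCCACAGAGGGTCTGTGGTCTAATCATGAATACCTGT
AACACCGAAGGGAGTTTATCACTCCGGAGTCTGACTCAGCATTCCAATACACTTTACCGGAAGTAAGGAC
TAGTCTAACTAGAGGCCTAGCCTCGTTGTTGATGCAAGTGTAATCGTCGTTGCAATCTGTCAGGAATTTT
ATTACGATTACCCACCCCTAGCGACGATTGAGCCTTCCTCAAATCCTTAGGGCGTCGATAACGCTCATGC
GCATACTCAAAACTGGGTAGAACCGTACAGTCTTGCCAACTGACTCACCGTTATGGTTGTTTCCCTGTAA
ACGAGGCGAACCTGCTTAAGCTTTCCCGCCACGACACACCCAGAGGCCGGATCTCCTTGGTTCGTAACAA
GGGAGCTTCCTCCCCCTAACCGAATGTAAATATGGCGTAGAGAGACAACACATCGTAAAATAGAAAAGCG
CGTGCATGTGACAACAGCCTCCACTTGGTGGAACCTAGAAGACGTAAGGATGACTAATAAGGAATTTATA
TATCACAGCCGCTGCTTGCCGGGCAAGCTTGATTACTCAGTACCTGGCTAGTTCGAGAGTTCCATGGTAT
TTTTCCCAGAACGCCATCATCGACAATTGTAGAGGTTATGCATCATCGCA
>L1-demo1#Retroelements/LINEs/L1-CIN4
TAAGAAATCCGGCGGACTGGCAGTCAGTTTTACCTTGTTGGTCAACAAGTGTTGATTTAAAACAACAAAC
TGATTCATAAGAGTTGATGTCGATGTGCGAGTCCAGCTAAGCTGATTAGTCGTTGGATCCGGCGACCTCA
CACTTGATCGTGCTTGGGTGATGTTACAGCCAGTGGACTGGCCAACAAGCGTATGCAATACAACCATCAA
TATCGAATGGATCTAAGTCTTTCTTAATCCACAAATTCCCTTCAGCATAGCTCCGTTAGGGACCATGGCA
AAGGGACACAATTAAAAATTACAGTACCTACCTAGCTATCTGGTTACCAAAAAGAACTGTACATGTTATG
CGTGCTCACCTCTGACGGTTGGGATCAAATAAAATTTCGGCAAGGTGCCGCTATTTTATGTGCGCAGCAG
CATTCATACTAATGAGCGACCGAATCTCTAAATAATAGTCCTGATGTAGCCCGTAACCCTGAGCCTACAT
ATTAGTCATTATCTTTTGACTTTAATCTACAACGACTCAGGATTGGGAACCTTCACCATCCATTCACCGG
AAAGGAAGTTCGTATAGTAGCTGGCCTGTAGGCACTTCGAAACTTGTGGCGTCCTAACGGCCCTATATCC
AGATGCGGAAAAAAATGAACCCGTGAGTAACCTGATTAGGAGTCTAATAGCTATCAGGAATTGTAACATG
GAGTATAACATCTTGGTCGAAGCAATCTTCTTAATGATCAACATTTTTCAGGCCTATAAGGATACATTTT
TACGCCACTGATACGTACAATAGCTTTAAACCCGTCTGGTCCCCATTACGTCAGATGCACATGCGCCCGT
ATTATACTACGATCCTGTTTTTTAGACCTGAGTCATAAAGATGACATGCGCCCCATGCTG
>SINE-demo1#Retroelements/SINEs
AACTTTAGTCCGGAGAGGCTGGTTCCGATTTGGGAAAGATATTGATGGTGCAGTCGTACCCCTACGCAAC
CGTGCGGGGGATTCGAGTCGGGCAGCTGACAGTTAACGAATTGCCCTTAGAAATGAATTCCGGAATTCCA
ATCAAGACACCTGAATTTGACCCCTTAGGTGTAAGTTCCGATGCAGCTTGGACCCATTAATGCGAGTTTC
GTTAGACAACGGGATGCAGCACAATGAGAACCAGGAGAAATTTAATTCTATCATGCAGGTACCGCCAATC
TTCTACTTGCGTTGGCCTAA
>EnSpm-demo1#DNATransposons/En-Spm
CATTTTATAACATACAATTCGACATGAGCACAAATAATTGAGCCGCGCTGGAAACGATGCAGTAGACTCT
GCCATAGAAAGCAGTGGCCGGCGTGAGGATGCACGGAAGATGCCAGCAAGAACCAGATATGGTGAGGAGC
AACCAGAGACGAATCTCTGTTGACTAAGTTGGTGTTAATTTATGTCGAATCTCTTAACTTTGAACGAAGC
TCTAAGTCTGCTTGTGGTTAATAAGACGCTCTTGTACTCGAATCTCCACTTCTCCCGACATGCTCTATTG
CTCTGGCCCGTTGCAAGTTGGGTGCCATCAGAAATAACGCTCAGCCCTCACTAGTGAGGGATGGAGAAAC
TGTGTCCTAATTGTTCGTACCACCGAATTAGTGGTTCGGAGGTTCACTGCACGAAATCTTCGGAGTCGAT
AACTGCCCATCCATGCTGATGTCTGCGCATTTGGTGCCTTGCGGGAACCCACCGGCTCCATTGCGAGACT
GTTCTGAGCACAGTGGGAGCGTTTTAGATGGATCATCTGTAGCGCCGCCCGGGATGTTGTATTGATTCAA
GCGAAAAGCCTTCCGGTGAACCCTTTGTGATTGCTGACCGTGTTCCTTATAGTAAACTGGTCTTCGAGAA
GCGTTTAAATGTCAACAGACGACATAGATAACAGCGATGGCTAACCTGGGAATATGAGTTAACTACGGCG
CTTTAATTAGCGACGCCGGTCAGCTTCGATAAGCTGTCCCACTAGGGATCGAGCGTCGCCCAATAGAATA
GACAACCCCTAGCCTCAGTGTGGGATAAAT
>Harbinger-demo1#DNATransposons/Tourist-Harbinger
TAGGCCTCCGTACAAAGTGTCATCATGCGTAACAATCGGCTCCCCCTAATCACGGAGACACTCATTAGTT
TATCACGAATAGGATAGTGTGACTTCGGGCCATAAGCGACACGTAAGCGCTCAGGAGCAGCTTCCTGGTC
TTATCCGTGTTTGTAGTAAGCCAATTTCCAACTTAGCTCGAATATTTCGTTCAGCAGCCCTTAAATTATA
CCTTCGAGTCGCCGTGTAGCGAAGCACCCCCAGACAAGCTATCAGGCTTCTTGTCAGTCAGGGCTCATAC
AAGTCAGGAGATTTAAAAGACGTTGACTTCCTACTCTTTCTTTGTGACGTGATTGAGGAATTTGACAAAC
GCTACGAATCGAGGCGGATCGAGTCCTCCGGCCAGAAAATCTCCTACTAGCTCAAGTGCGATGCTGGGCA
CCAACGTGAGGCAGTATTAGAAGTATAAAAGTATACTTAGCTGACTGCGTTTGTGGTGCTGACGCCTTAT
GTCCATCTCA
>MuDR-demo1#DNATransposons/MuDR-IS905
TGATTTAAGTTATCTTGAGCCGCATGCAGTATTACGAGTTCTGACGTTCTGTCCGTATAGCTACCCGGCA
TGCAGTAGCTGACGTGTTGACCGTCGTGCGATGGATTGGTGGCTCTTGTGTAGAAAGCTTCTCCCCTCTG
CCAAGCTCCTCGTTCGCTCGTAAGGGTCTAATAGAATATCCAACAAAGTTGCGACCCAATGCGAGTACTT
GACAAAATGCACCATCGAGGCGCGAGGTATAAATATGTATAAATCTCTAATGTTCCTTTAGAGGAGTTAG
CTCTCAGCTGAACGGGGCAAAGGAACACATGGTGAGACATATCCGCGTGTACCCTTCTGGGGGCAGATAT
GAGACTTCGCGTCATTGAGCATCTGATCGGCGGAGACAAAGTAGTGATTTGGCGCCTGCCAGCAATAAGG
GATAGCTGTATTTAGACCGTTGGACCAAGATCGCGGCTCTTGTAATGCAACGGACCTAGAACCGATGAGG
CAGCTCCAGAGAATGGACGATTATCGCCGTCGAAGTTCTGGAGTCAAACATCTTTAATGATCTCGTGTGT
ACCTACGTCGCAAGATCTCTACAATGCGGAACCTATAGCCGTACCTTTTAGTCCGACTGGCGGTAACCCA
GGCTCCGTTGTATGGTTAAACTGTGCAACATTAAAGACGAATCTTGGGGTATCAGGTTCATTAAGGGGCA
>Sat-demo1#Satellite
TAGGACGATGTCTAGCCGGGTGGAGTTATCCGAGTGACTTGGAGCGCACCAGTTAGCCAGCGTCGCAAAT
AATTTCTTCCACGTCGATTCACAACAGCTATCACGCTACCAACGGAGTTTTTCCTAGCATGAACAAAGCG
CTAGACCTCCAATTCCATATGAAGGAATTGACCATGTCTCGCAGAGTATCCCTTAAGATATTCTGATCAC
GAGTTTTTAATAATGCTCCGACTTTATCAGGAGGGGCATTACTCCGTATCTGGGCTTCGTGCGCTCAGAT
CGGGGGAAGTCCCATACCTGATGTATACCCCCGAGCTTTATTTGATTAAGCCACACCGCCATTACTCAAG
TACGTTCGGT
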