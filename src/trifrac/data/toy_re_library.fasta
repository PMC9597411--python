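>RE01
CGCCTAAGGGTCCGCAGAGGGAGCGGGGTCACCCTGACGAGTACGCCTTGCGGTGTTACA
>RE02
GTCTTCTCTGAGCTCCGTCTGTAGGTCCACCTTTTGTAGGTGAGGTGCAAAGGTGGAGGAGCGTCATTCA
GTGTTATCCTAGTAGGGACC
>RE03
GCTTTACCTGTGCCGCCCCGACTTAAGTCCCTCCAACATGAAACAGGGTTCTTAACTTGCATAGGATCCA
GGACTGTGTTAGTAGTTACCTGATCCCTTAGATGCGATGAAACTATAGTCA
>RE04
ATGCAACGCCGCACGGCATGATTCTATTGATTCGGGATGTCACGGCGGACTTCGACGGTCCGCGCATCTT
TCTTCCAGCAGCGTCGAGTCGATAAATGCTCTTCGTCCGGTATACCCGCAGCAATTGTTCAAAGCGTTGC
GATAACAGACGT
>RE05
AATGGCTCTCTTGGCGACGCTCCTTGAAAGTCAAACACATACCCGCTCACCTCCTGAGACGTACCTTTTT
AGACTCAGATAAGTTAGATGTTAACGGGCCTACGTCGTGTTGCCCTCCCTTGGTAGCCCCAAGTAAGCTC
CGTGAGATTCGAGCTGATACTGAATTAAAGTGGCACGGTGACG
>RE06
CCAGCGACTGTCCCCGGCTAAAGCGGGCCTGAGTGGAGTCATTTAGCAGTGTCCTCATAGGTATTCCTAC
GCCACGGGTGCTCTGAAGCACACCTGATGTAGCCGACAGCGCACCGCGTCAGGAGGCTGACCCGATAAAA
GCAATGACTTTGACTGGGTTATACCCTCGTAGGGGGTGGGTCGGCGCGTCCTACTGCCAGACTTAATTCT
CTCT
>RE07
ACTGCAATCTTCTATGGTGCACGGTTGGAATGTACTAACACGAACCGGCCCCTGCAAATGGAGAAAATGG
CGCCCACACCCGGTCCAAATGGTTGGATCGCTGATGACCTCGGACTGAATATTCTCACCAAATCCCATTG
CTCCAAGCTCACAACAGGAATACCACCGCCGGTATCCTCGTGGGCTGCAACCAAAAGTCATAAGGAATAG
CTAAGTAGATCTTCGAAACAATTAACATATCAGGT
>RE08
ATACGTGTGACCTACCACGCAGAGGAGTGCGGGTGCCGGTAAGTTGAAATCTATCAGATATCCATTCCAC
TTATCCACTAAGTGGCAACTGGAGGTAAGGGTCACTCGAATCTAAGACGCCCCGTCTAGTCTCGTGGGCA
AAGAAGGGTGCGTGTTTAGTCCATTGTTCATGGTCTCAACGTGAAGGAGTCTCAGGCAGGAGTCACGGAT
CTCCACAGACGAGTCATCCAGGCTAGGGCCTCATAGTGTCAAATTCGCATCACATTTGCACATCTG
>RE09
ACAGCGTGCTAGGCAGTTCGACTCGACGATATCACGCTCAAGAGATCGCTCAGAGTGCGGTTCTGTGCAG
GTAAGCGTTGGTTGTGGTGGCAAATCGTAGTGCCCAAATGCCGGGGCGCGAGTATAGAGGAATCTGGCAA
CATCAAGACGCGCGCGGTATTCCGAACGCCCTCGCTAGCCATGCCAGCTAGTGCCCAAGTATGGAGCTTC
GATCTACATGATTGAATTGTGCGCCCGGATATCCGATGTCTATCAGTGGCAATGCGTATGTGAGCAGAGA
ACGCAAGTGGGATTGGACACGGACGAA
>RE10
CACCCTGGCAAGGCCAGCTATCGCAATTATAGCAATAGGGCTACCTTGAGGTAACACAGAGTTGCCAGCG
GTTATAGCAACCGAGTGATTTCCGAGCAGGGCCTGAAGGGACCCTAAGTTTGGCCTTCCACCTGTAGAAA
AGTTTTCAGCCTCCCGGCAAACCCTTAGGGCTTTATATGACATTGTCCGGATAACTCTGCAGTTTAAGTT
CGACAGGAATCAGTTAATTTCCCGTGCACAAAGCGCCCGGTCAAAACGGGTCATTATATAGTGCTAGTCG
TACTCCCACCGTGCTCACGCCATTACGTTGATGCTCCTGAGCGGCGGAATAACGACAA
>RE11
GTCATCAAGAATTGTGAGCAGGAACTCCCACATACGGCCGACAACGGTCCCTGACGCAAGCAGGAACAGT
TGGCACTACGCGATCTAATTATATTACTTTAAGTAAGGGGACCGACCCCATTAAAATTATTGCCTTCAAT
CACCCCAAAAAGGTCTGGTATCATAGAATCCAGATATGACTTCTAGCGCTCCATGGTGACACTAGCTTCA
ACACGCGCTCGTGCTTTCTTGTGCGTGGACATCATGCGAAAAGTGCCGTCACAGCCTAGGCACTCTTGCT
CGCTCGTTGCCGGATGAGTCAAAAGACCCGGACGATAGATCTCGGCACGCCGTGCGTGGCACTTGACTTC
AGGTTAACAGCACCGCGTA
>RE12
TTTCACTGCACCATAGGAATGAATCCGGTTCCTAGTCTCGTAGTTCATCTAGGCTACGGTGTAGCAAAAT
CCGATGTGCACAGTGCACGTTAGGCTGGACAGTATGCAGAGGGCATCTACAAGTATCTCGTCTCATTATT
GCCTTTTCGAAGTGTGATCGAGTTTAGATGGCGTCTCTTCGGCAGACGTCGTACTATTAGCCGTAGGAAG
TGGTCTCTAGCATGGACGCGGACCAAAATTGCAGCCGCCCAGATCATACAGATTCGAGACATCTAAGCCA
CTGTCCACCTGCAAGGATTGCACGGGCGATATCGCACGCTGTCACCCTGCACACGTGAATCGGAAGCCAT
AAAGTAGCTAGAGGTCCTCCCGTTCATGCCGCGTTCTCCTACAAATCCAA
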