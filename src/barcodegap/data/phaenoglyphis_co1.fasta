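>P_belizini_CO1
AATTTTATATTTTATTTTTGGAATTTGGTCAGGAATAATTGGATCTGCTTTAAGAATAATTATTCGTATAGAATTAGGAA
CTCCATCACAACTTATTGGAAATGATCAAATTTATAATTCAATTGTTACAGCTCATGCTTTTATTATAATTTTTTTTATA
GTAATACCTATTATAGTTGGAGGATTTGGAAATTATTTAGTTCCTTTAATATTATCAGCTCCAGATATAGCATTTCCTCG
TCTTAATAATATAAGATATTGATTATTATTACCAGCTTTAATTTTATTAGTATCAAGAATATTTATTGATCAAGGAGCAG
GAACAGGGTGAACAGTCTATCCTCCTTTATCTTCAAATTTAAGACATTCAGGAATTTCTGTTGATTTAACAATTTTTGCT
TTACATTTAAGAGGAGTTTCTTCAATTTTAGGAGCTATTAATTTTATTACAACAATTTTAAATATACGAGTAATTTCAAT
AGATAAAATTTCTTTATTTATTTGATCAATTTTTTTAACAACTATTTTATTATTATTATCTTTACCAGTTTTAGCTGGAG
GTATTACAATATTATTATTTGATCGTAATATAAATACTTCATTTTTTGATCCAATAGGAGGAGGGGATCCAATTCTTTAC
CAACATTTATTT
>P_evenhuisi_CO1
TTTATTATATTTTATTTTTGGAATTTGGTCAGGTATAATTGGATCCGCCCTAAGAATAATTATTCGTATAGAATTAGGGA
CCCCTTCTTCATTAATTGGAAATGATCAAATTTATAATTCAATTGTAACAGCCCACGCTTTTATCATAATTTTTTTTATA
GTAATACCTATCATAGTCGGGGGATTTGGTAATTATTTAGTCCCATTAATATTAAGGGCCCCAGATATAGCTTTCCCACG
TTTAAATAACATAAGTTTTTGATTATTGCCCCCTGCTTTATTTTTATTAGTTTCTAGAATATTTATTGATCAAGGGGCTG
GAACTGGATGAACGGTTTATCCGCCCCTTTCATCTAATTTAGGACATTCAGGAATCTCAGTAGATTTAACTATTTTTTCT
TTACATTTAAGAGGTATTTCTTCAATTTTAGGTGCAATTAATTTTATTTCAACAATTTTAAATATACGAATTATTTCCTT
AGATAAAATTTCCTTATTTATTTGATCTATTTTTTTAACAACTATTTTATTATTATTATCATTACCTGTATTAGCCGGAG
GAATTACAATATTATTATTTGACCGAAATTTAAATACCTCTTTTTTTGACCCTATAGGAGGAGGTGATCCAATTTTATAC
CAACATTTATTT
>P_longicornis_CO1
TTTATTGTATTTTATTTTTGGAATTTGATCGGGTATAATCGGGTCAGCTTTAAGAATAATTATCCGAATAGAATTAGGAA
CCCCATCTTCATTAATCGGTAATGATCAAATTTATAATTCAATTGTTACAGCTCATGCTTTTATTATAATTTTTTTTATA
GTCATACCAATTATAGTAGGGGGATTTGGAAATTATTTAGTTCCTCTAATATTAAGTGCTCCTGATATAGCTTTCCCACG
ATTAAATAACATAAGTTTTTGATTATTACCTCCTGCTTTATTTCTATTAATTTCTAGAATATTTATTGATCAAGGGGCTG
GAACTGGATGAACTGTTTATCCTCCTCTTTCATCTAATATAGGCCATTCAGGAATTTCAGTAGATTTAACTATTTTTTCT
TTACATTTAAGGGGAATTTCTTCTATTTTAGGGGCTATTAATTTTATTTCAACAATTTTAAATATACGAATTATTTCTTT
AGATAAAATTTCTTTATTTATTTGATCTATTTTTTTAACAACTATTTTATTATTATTATCATTACCTGTATTAGCAGGAG
GAATTACTATATTATTATTTGATCGAAATTTAAATACTTCTTTTTTTGATCCAATGGGAGGGGGAGACCCTATTTTATAT
CAACATTTATTT
>P_salicis_CO1
TTTATTGTATTTTATTTTTGGAATTTGATCAGGAATAATTGGATCAGCTTTAAGAATAATTATTCGAATAGAATTAGGCA
CCCCATCTTCATTAATTGGTAATGACCAAATTTATAATTCAATTGTTACAGCTCATGCTTTTATTATAATTTTTTTTATA
GTTATACCAATTATAGTAGGAGGATTCGGTAATTATTTAGTTCCTTTAATATTAAGGGCTCCTGATATAGCTTTCCCACG
ATTAAACAATATAAGTTTTTGATTATTACCCCCCGCTTTATTTTTATTAACTTCTAGAATATTTATTGATCAAGGAGCTG
GAACTGGATGAACTGTTTAYCCACCTCTCTCCTCTAATTTAGGCCATTCAGGGATTTCAGTAGATTTAACTATTTTTTCT
TTACATTTAAGGGGAATTTCTTCTATTTTAGGAGCTATTAATTTTATTTCAACAATTTTAAATATACGAATTATTTCTTT
AGATAAAATTTCTTTATTTATCTGATCTATTTTTTTAACAACTATTTTATTATTATTATCATTACCTGTATTAGCAGGAG
GGATCACTATATTATTATTTGATCGAAATTTAAATACTTCTTTTTTTGATCCAATGGGAGGAGGAGACCCTATTTTATAC
CAACATTTATTT
>P_stricta_CO1
GATATTATATTTTATTTTTGGTGTGTGATCTGGAATAATTGGGTCATCTTTAAGATTAATTATTCGAATAGAATTAGGAA
CACCAAACCAATTAATCGGAAATGATCAAATTTATAATTCTATTGTTACTGCYCATGCTTTTATTATAATTTTTTTTATA
GTTATACCTATTATAGTAGGAGGGTTTGGTAATTATTTAATTCCTTTAATATTATCCGCCCCCGATATAGCTTTCCCTCG
TTTAAATAATATAAGATTTTGACTTTTACCTCCTGCTTTATTATTATTAACATCTAGAATATTTATTGATCAAGGGGCTG
GAACAGGGTGAACAGTGTATCCTCCTTTATCATCTAATTTAGGTCATTCAGGYATTGCAGTTGATTTAACAATTTTTTCT
TTACATATAAGAGGAATTTCATCAATTTTAGGGTCAATTAATTTTATTACAACAATCTTAAATATACGAATTGTTTCAYT
AGATAAAATTTCTTTATTTATTTGATCCATTTTTTTAACAACAATTTTATTGTTATTATCTTTACCAGTATTAGCTGGAG
GTATTACTATATTACTTTTTGATCGAAATTTAAATACYTCTTTTTTTGACCCTATAGGAGGAGGRGATCCTATTTTATAY
CAACATTTATTT
>P_villosa_CO1
AATTTTATATTTTATTTTTGGAATTTGGTCAGGAATAATTGGCTCTGCATTAAGAATAATTATTCGTATAGAATTAGGGA
CTCCTTCACAATTTATTGGGAATGATCAAATTTATAATTCAATTGTGACAGCTCATGCTTTTATTATAATTTTTTTTATA
GTGATACCTATTATAGTTGGAGGATTTGGTAATTATTTAGTCCCTTTAATATTATCAGCACCAGATATAGCGTTCCCTCG
TCTTAATAATATAAGATACTGATTATTATTACCAGCATTAATTTTATTAGTTTCAAGAATATTTATTGATCAAGGGGCAG
GAACAGGATGAACAGTTTATCCACCTTTATCTTCTAATTTAAGACATTCAGGAATTTCAGTTGATTTAACAATTTTTGCT
TTACATTTAAGGGGGGTTTCTTCAATTTTAGGGTCAATTAATTTTATTACTACAATTTTAAATATACGAATTATTTCAAT
AGATAAAATTTCTTTATTTATTTGGTCTATTTTCCTAACAACAATTTTATTATTATTATCTTTACCGGTTCTAGCTGGAG
GAATTACAATATTATTATTTGATCGTAATATAAATACTTCTTTTTTTGACCCTATAGGAGGAGGGGATCCAATTTTATAC
CAACATTTATTT
>P_xanthochroa_CO1
GATTTTATATTTTATTTTTGGGATTTGGTCAGGAATAATTGGCTCAGCTTTAAGAATAATTATTCGAATAGAATTAGGAA
CCCCTTCTCAATTGATTGGTAATGATCAAATTTATAATTCAATTGTAACAGCTCATGCTTTTATTATAATTTTTTTTATA
GTTATACCAATTATAGTAGGTGGGTTTGGGAATTATTTAATTCCTTTAATATTATCAGCCCCTGATATAGCTTTCCCACG
TTTAAATAATATAAGATTTTGGTTATTAATCCCAGCTTTATTTCTATTAATTATAAGAATATTTATTGATCAAGGGGCAG
GGACTGGATGAACTGTTTACCCTCCTTTATCTTCAAATTTAGGTCATTCTGGGATTTCTGTTGATTTAACAATTTTTTCA
CTTCATTTAAGAGGAGTATCTTCAATTTTAGGGGCAATTAATTTTATTTCAACAATTTTAAATATACGAATTATTARAAT
AGATAAAATTTCATTATTTATTTGATCAATTTTTTTAACAACAATTTTATTATTATTGTCTTTACCTGTTTTAGCTGGAG
GTATTACTATATTATTATTTGATCGAAATTTAAATACTTCTTTTTTTGACCCTATAGGAGGAGGAGACCCAATTTTATAC
CAACATTTATTT
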