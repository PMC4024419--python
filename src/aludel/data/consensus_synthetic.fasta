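>AluSyn synthetic ~300 bp Alu-like consensus (randomly generated stand-in, not a Repbase sequence)
GCGCGAACCGATAGCATATGCCAAAGTCTCCCATCCAGTATCCTCAGCCCGTACACATTC
ATAAGAACCTACTACAGAGAAAATTTTAAATGAATATCATCTGCGGGTAAGAATACTAGT
GATCGCGTATTCAGCTCCTAAACCATTGGTCAGGTGAAATGAACCACCAGACGCATGGCC
GCTTGTCTGAGAAGGAAGCTGATCTTCCTCAAGGAAAAATGAAGTAAATGGATTTTCGGA
TATAAGGTGCACGCCTCCTACTGTCCAGGCAGTTCTTCTCAGTCATGGGTCAAAGGAATA
>L1Syn synthetic ~1 kb L1-fragment-like consensus (randomly generated stand-in, not a Repbase sequence)
CGTGAGGGAACATGCGGGCCTATTTATAGGCGGACCTGAAAGGAACCGACAGAGCTGCAC
CACCGATTTCGCGGGTTGTCTTGCTTAACACGCGCACGGAGCACAACTACGCTTGTAGTG
GCGTAGCCGCGTCATTGGTTTATGCCACTTTTGTGACCAACCCCGTTAGATGGCCCTAAG
ACTCGGTGTTATTTGAAACTGAGGTGAGGCCTAGATCGGGTTTGTCAAGGAAGTCTATCT
CATCTAGGCTGCCGCCTTCATCCATGAACAAGTAATACCACGACGGAACAAAAGGGTGTC
TCGTAGGTGCCAATGCGGCGTGTCGATCGAGGCGTCCACGCCACATTGAGCTAGTATCAG
AGACTCTGCTACACAATGGGATAGTTCTGGATGAGCTGACCGGTGGCCAAAGATGTTAGT
GTCTCTTACTAGCCAGTCCACATACTCAAAAGGTACAGTCCTCCAGCCTTAAAGCCCCCG
TATGCAGAAGGATAACCTGCATCGCGGCCTAATACAACACATAATCGTGCTAGCGACATC
ATCCCAACAGTGGGCTAATATTGGCTGCGCGCCTCTTCACGACACAGCTCACGAATAAGA
CCCCACATGCTCCTGAGACATTTGGGCGAAGCACCCTCACGTGCTGAAATGGGAACAGTT
CCTTAACTTCCGCCAATTTCGCGATTAACTCCTCCTACGCACTCTGGTTCTGATTCACTT
TTTTGCACATTAACGTATTCTCGCGATGCTATGGTCTCGGGAACGGTTGGATAGATATCA
ACCCTAGCTTCGCGACGGCGACTAGCTAAACAGAAGCCCCCTCCCACGAAGCAAGCGTTC
GGGGTAAACATAAAATTCCGATAGCGAATGGCTCGGAGTTCTGACTCGACTTGTCTTAAA
TACTGTACCTGGAAACGGTTCGCGAAGATCGCTTACTAGCGTACCGGGTCAGAGTTCGGG
CAGATTCCCGATTTACCCCCACCATATCCATATTTAGTTT
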