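>X79547_dloop_synthetic positions=15440..16642 synthetic stand-in: true alleles only at the 42 variable sites
CGCGCATGGTTCGTAGTGTTCAATGCAGCTAGGCTGTTCGCACCTGGTGAAATCTTACTCTAGCGGGATA
ACTGCCATGTAAAGTCTGGGCACACACAAGATCTCGTCAGGGGAAGGGGTGCAGTGATAGATAGCGCGGA
CCTCGGGTTCCCGTCCTTACCTCTTTCGACAGCTCGGTTCGGCCAGTGCGTGTAACCAGAGTTTTGTCAA
AGCAGCGCCGTGAAAGGACCCCAGCCCACTGTTGACGTACTTCATTAACTATGTGGTAGCTGAAGTTCGG
GCGACTACAGTCTAATTATGACGAGCTCGTGAAAGCTCGGGTGTGCTCATCCACCGAATTTAAGTGGTCG
GGCGTACCTGTGGCTCCCGACACGCTATCACCGAGCAAAGGGGACCCGCAAATGTAAATCGTGCCCTTTA
CGACTAATCCCCCGGCACACCGACAATATCTACGCTATGTGACAGCCAGGCGGAGATCCATTTTAGTCAC
TACATATTTCCTAGAACTTGTGGTTCACCTGATGCCTGGTTTTTCCGTATTTGGGTTTCATGTGTATCTA
TTCGGCGAGTGGCCGCCGAGGCAGGACATATCCTGCCAGCAGTCTCCAGACGTATATACGATCCACGCTA
TTGACGGTAAACCGCCTGACCGAGCCAAAAGCGCCTATTAAATATTGGATGCAACTACTCGCAGAATTAC
TCTCCAGCAGGGCTATAATCGTCCTCGGTTTTTGGACTAGTAATCACGAAGAGTCTTCCTCCAAAGATAG
TACTGCCACTTTCCAAAGTGACTCAGAATTCTGCCGTAAAACGACACAACAGAGGGTCCGTTGCGTGCCA
CTGTGGGAATGTTATAACCGCTTCATCTCGTTAGCGTATCCGTATCGCGAAGCCTAGTATCAACCGATAG
GTAGGCTGGCCAGTAGTAGAATAGCCCCATTAGACTCAGGCTTCTTGCCATCGTCGAGGCCAAACCTCAA
AGAGTTAATATCCGCCATAGCTCTCCATAAACGCACCTAGACGATTTCGTCTAGTTTTAATTATGGTAGT
GGAGCGTCTCCCGGCACCAGCTAGATTGCTCACAGTAGCTCTTCATATGCTGGTGTTAGTGCTCACGTCC
ATAGCGATAATCTCTACAGAAGCCTCCAAAACCCGACAAGTCTCTGTTTAGACCGGAACCTACGCTCCGA
AGCAGACTGAAAT
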