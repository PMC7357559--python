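name	arm	mature	mean_tpm
mir-10399	5p		14.04
mir-1246	5p		0.96
mir-1248	5p		2.55
mir-124-3	3p	TTAAGGCACGCGGTGAATGCCA	0.22
mir-1294	5p	TGTGAGGTTGGCATTGTTGTCT	1.04
mir-1301	3p	TTGCAGCTGCCTGGGAGTGACTTC	30.95
mir-1307	5p	TCGACCGGACCTCGACCGGCT	1.02
mir-1307	3p	ACTCGGCGTGGCGTCGGTCGTG	543.87
mir-1327	5p	TAAAAGGCTGTTAAATGGTGAT	1.08
mir-138-1	5p	AGCTGGTGTTGTGAATCAGGCCG	2.20
mir-1468	5p	CTCCGTTTGCCTGTTTTGCTGA	3.87
mir-151b	3p	TCGAGGAGCTCACAGTCT	3.50
mir-1839	5p		249.11
mir-1839	3p	AAGGCCTACTTATCTACCAAC	1.85
mir-1843	5p		33.89
mir-1843	3p	TCTGATCGTTCCCCTCCATAC	51.60
mir-1976	5p		1.60
mir-199b	5p	CCCAGTGTTTAGACTATCTGTTC	230.72
mir-200b	5p	CATCTTACTGGGCAGCATTGGA	0.79
mir-200b	3p	TAATACTGCCTGGTAATGATGA	13.71
mir-219b	5p	AGATGTCCAGCCACAATTCTCG	1.33
mir-2355	3p	ATTGTCCTTGCTGTTTGGAGAT	10.11
mir-3074	5p	GTTCCTGCTGAACTGAGCCAG	11.20
mir-3074-2	5p	GTTCCTGCTGAACTGAGCCAG	11.20
mir-30e	5p	TGTAAACATCCTTGACTGGAAG	3875.85
mir-30e	3p	TTTCAGTCGGATGTTTACAGC	1023.80
mir-3120	5p	CCTGTCTGTGCCTGCTGTACA	4.30
mir-3120	3p	CACAGCAAGTGTAGACAGGCA	9.52
mir-3155a	5p	GCTCCCACTGCAGAGGCTGG	0.44
mir-3155a	3p	CAAGCTCTGCAGTGGGAACTGA	7.83
mir-3158	3p	AAGGGCTTCCTCTCTGCAGGAC	14.74
mir-3158-2	3p	AAGGGCTTCCTCTCTGCAGGAC	14.74
mir-3160-1	3p	AGAGCTGAGACTAGAAAGCCCA	0.72
mir-3160-2	3p	AGAGCTGAGACTAGAAAGCCCA	0.72
mir-3164	5p	TGTGACTTTAAGGGAAATGACG	0.97
mir-3164	3p	CCGTTTTGCTTGAAGTTGCAGT	0.56
mir-3174	5p	TAGTGAGTTAGAAATGCAGAGC	3.28
mir-3191	3p	TGGGGACGTAGCTGGCCAGACAG	1.24
mir-320b-1	3p	AAAAGCTGGGTTGAGAGGGCAA	119.04
mir-320c-1	3p	AAAAGCTGGGTTGAGAGGGT	41.88
mir-320d-1	3p	AAAAGCTGGGTTGAGAGGA	25.86
mir-320d-3	3p	AAAAGCTGGGTTGAGAGGA	25.86
mir-320e	3p	AAAAGCTGGGTTGAGAGGGTGA	2.08
mir-326	3p	CCTCTGGGCCCTTCCTCCAG	7.38
mir-3609	3p	CAAAGTGATGAGTAATACTGGCTG	1.38
mir-3613	5p	TGTTGTACTTTTTTTTTTGTTC	115.70
mir-3620	5p	GTGGGCTGGGCTGGGCTGGGCC	0.81
mir-3691	5p	AGTGGATGATGGAGACTCGGTAC	0.89
mir-371b	5p	ACTCAAAACATGGCGGCACTT	1.38
mir-378g	5p	ACTGGGCTTGGAGTCAGAAG	0.40
mir-3913-1	5p	TTTGGGACTGATCTTGACACTCT	8.91
mir-4485	3p	TAACGGCCGCGGTACCCTGA	0.38
mir-4659a	3p	TTTCTTCTTAGACATGGCAGCG	0.93
mir-4661	5p		0.75
mir-4676	5p	GAGCCAGTGGTGAGACAGTGA	16.80
mir-4684	5p	CTCTCTACTGACTTGCAACATA	0.71
mir-4684	3p	TGTTGCAAGTCAGTGGAGAGGT	0.56
mir-4791	5p	TGGATATGAAGACTGAAA	0.63
mir-486-1	5p	TCCTGTACTGAGCTGCCCCGAG	7013.65
mir-486-1	3p	CGGGGCAGCTCAGTACAGGAT	332.08
mir-4999	5p	GCCGTATTGTCAGGTAGTGATA	1.41
mir-4999	3p	TCACTACCTGACAATACAATAT	0.26
mir-548ad	5p	AAAAGTAATTGTGGTTTTTG	2.20
mir-548at	5p	CAAAAGTTGTTGCGGTTTTGGC	1.34
mir-548av	3p	AAAACTGCAGTTACTTTTGC	0.36
mir-548ay	5p	AAAAGTAATTGTGGTTTTTGC	3.98
mir-548l	3p	CAAAAACTGCAATTACTTCTGC	1.08
mir-5690	5p	TCAGCTACTACCTCTATTAGG	4.21
mir-610	5p	TGAGCTAAATGTGTGCTAGGA	8.26
mir-641	5p	AAAGACATAGGATAGAGTCACCTC	1.06
mir-6501	5p	AGTTGCCAGGGCTGCCTTTGGT	1.74
mir-6503	5p	AGGTCTGCGTTCTAATCCCCA	7.58
mir-6503	3p	GGGACAAGGATGCAGACCTCC	18.52
mir-6503-2	5p	GGAGGTCTGCATTCTAATC	0.17
mir-6503-2	3p	GGGACAAGGATGCAGACCTCC	12.61
mir-6516	5p	TTTGCAGTAACAGGTGTGAGCA	0.32
mir-655	3p	ATAATACATGGTTAACCTCTTT	2.35
mir-6731	5p	TGGGAGAGCAGGGTATTGTGGA	1.20
mir-6735	5p	AGGGCAGAGAGCACAGGAATCTGA	1.14
mir-6735	3p	AGGCCTGTGGCTCCTCCCCCAG	0.09
mir-6813	5p	CAGGGGCTGGGGTTTCAGGTTCT	0.69
mir-6816	3p	GAAGGACCTGCACCTCCGCCCACA	0.82
mir-6866	5p	TTAGAGGCTGGAATAGGGATT	0.69
mir-7155	3p	TGGCCCAAGACCTCAGACC	0.68
mir-744	5p	TGCGGGGCTAGGGCTAACAGCA	1140.67
mir-744	3p	CTGTTGCCACTAACCTCAACCT	1.71
mir-7848	3p	CTACCCTCGGTCTGCTTACCACA	18.23
mir-935	3p	CCAGTTACCGCTTCCGCTACCGC	1.44
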