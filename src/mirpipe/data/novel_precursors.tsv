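name	precursor	mature	reported_mfe
ssc-mir-1343	GGCTTCGGTGCTGGGGAGCGGCCCCCGGGCGGGCCTCTGCTCTGGCCCCTCCTGGGGCCCGCACTCTCGCTCCGGGTC	CTCCTGGGGCCCGCACTCTCGC	-50.3
ssc-mir-2320	TGTCCCCATGGCACAGGGTCCAGCTGTCGGCTGTAATACCCGATGGGTCGATGATGGTCCCTGTGTTTGGGGCG	TGGCACAGGGTCCAGCTGTCGG	-37.7
ssc-mir-2366	CCCCAGGGTCCTCTTGTCTGAGCCCCAGAAAGAGGAGAGAGCGCTGGGTCACAGAAGAGGGTCTGGGGG	TGGGTCACAGAAGAGGGTCTGG	-31.6
ssc-mir-2411	GAGGCAATGTGGAGTGACTGTCAGATGCAGCCATCAGAATAGGTGATTTGGCTGAACTGTCATACTCCCACATCCTC	GGAGTGACTGTCAGATGCAG	-29.2
ssc-mir-2483	GAGTGAAAAGTTCCGTCAACCATCCAGCTGTTTGGGGTGATGCAAACAAACATCTGGTTGGTTGAGAGAATTTTTTACTT	AAACAAACATCTGGTTGGTTGAGAGA	-37.3
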