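# Conserved control-region segments of six ranid species (published D-loop survey):
# termination-associated sequence (TAS), H-strand replication origin (OH) and the
# conserved sequence blocks CSB-1/2/3. Sequences are H-strand, 5'->3'.
species	motif	sequence
Rana omeimontis	TAS	ATTAATCTATATAGGTA
Rana omeimontis	OH	AGGAATTTTAGGGGGATGCGATCCTCACCAACTTTAAGAAACCGTTCCTACTGCATATTAGTCAT
Rana omeimontis	CSB1	TCTTAATTAATGCTCGATTGACATA
Rana omeimontis	CSB2	CCCCCCCTTTCCCCCCC
Rana omeimontis	CSB3	GTAATTGCCTTAAAACCCCCCC
Rana catesbeiana	TAS	ATTAACAGTTATGTACA
Rana catesbeiana	OH	GGTAGTTTTTTTTGGGGTCCTTTCATCAGCTACTCCCAGTGGGCTCACTCCTAAACAACCGG
Rana catesbeiana	CSB1	TTTTAATTAATGTTAGATTGACATA
Rana catesbeiana	CSB2	CCCCCCCTTTCCCCCCC
Rana catesbeiana	CSB3	TAGTTTGCCTTAAAACCCCCCC
Pelophylax bedriagae	TAS	AATCCCCACTATATGTA
Pelophylax bedriagae	OH	GGTATTTTTTTTTGGGGGGCCTTTCATCAGCTACTCACAGTGGGGACACGGCTTACGGTCAAGGTTAG
Pelophylax bedriagae	CSB1	TTTTAGTGAATGCTAGAATGACATA
Pelophylax bedriagae	CSB2	CCCCCCCTTTCCCCCCC
Pelophylax bedriagae	CSB3	TAGATTGCCTTGAAACCCCCCC
Odorrana hainanensis	TAS	AATCACCATTAATATATA
Odorrana hainanensis	OH	AATTCATCCCCACAGGGCCAGATCACGGGCATTAGTCCAAGGGTGGACATATTATGCAGCTGCA
Odorrana hainanensis	CSB1	TTTAAATGAATGCTCGAATGACATA
Odorrana hainanensis	CSB2	CCCCCCCCTTCACCCAA
Odorrana hainanensis	CSB3	TCTATCGCCCCAAGTATCGCCCC
Glandirana tientaiensis	TAS	CTTAACAATTTTATGTA
Glandirana tientaiensis	OH	ATTTTTCTTTTGGGGGGAGATCTCAACCAGCATCTCCAGTGGGCCCACGACATATAGTCCAC
Glandirana tientaiensis	CSB1	TAAAAATGAATGCTAGATTGACATA
Glandirana tientaiensis	CSB2	CCCCCCCTTTCCCCCCC
Glandirana tientaiensis	CSB3	TAGATTTGCCTTAAAACCCCCCC
Amolops mantzorum	TAS	ATTAACCATAATGTATG
Amolops mantzorum	OH	GGTATTTTTTTTTTGGGGAGCTTTCACCTGGCAACTCAAGTGGGTTCACGACATATAGTCCGGGTTGGACAT
Amolops mantzorum	CSB1	TATTAATATATAATAATCATAAATT
Amolops mantzorum	CSB2	CCCCCCCTTTCCCCCCC
Amolops mantzorum	CSB3	CAAACTTCCATAAAAACCCCCC
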