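# Published codon usage of the 13 Rana omeimontis mitochondrial protein-coding genes
# (3,755 codons; vertebrate mitochondrial code). `rscu_published` is the value as
# printed in the source table; mitokit recomputes RSCU from the counts.
codon	aa	count	rscu_published
UUU	F	127	0.97
UUC	F	135	1.03
UUA	L	110	1.05
UUG	L	29	0.28
UCU	S	65	1.47
UCC	S	72	1.62
UCA	S	66	1.49
UCG	S	10	0.23
UAU	Y	48	0.83
UAC	Y	67	1.17
UAA	*	3	1.71
UAG	*	1	0.57
UGU	C	10	0.67
UGC	C	20	1.33
UGA	W	77	1.43
UGG	W	31	0.57
CUU	L	124	1.18
CUC	L	168	1.6
CUA	L	135	1.28
CUG	L	65	0.62
CCU	P	47	0.91
CCC	P	101	1.96
CCA	P	49	0.95
CCG	P	9	0.17
CAU	H	28	0.53
CAC	H	77	1.47
CAA	Q	65	1.63
CAG	Q	15	0.38
CGU	R	8	0.43
CGC	R	25	1.35
CGA	R	36	1.95
CGG	R	5	0.27
AUU	I	129	0.91
AUC	I	156	1.09
AUA	M	101	1.29
AUG	M	55	0.71
ACU	T	65	0.89
ACC	T	111	1.52
ACA	T	101	1.38
ACG	T	15	0.21
AAU	N	60	0.92
AAC	N	70	1.08
AAA	K	75	1.79
AAG	K	9	0.21
AGU	S	17	0.38
AGC	S	36	0.81
AGA	*	2	1.14
AGG	*	1	0.57
GUU	V	50	0.93
GUC	V	67	1.25
GUA	V	63	1.18
GUG	V	34	0.64
GCU	A	87	1.06
GCC	A	156	1.91
GCA	A	64	0.78
GCG	A	20	0.24
GAU	D	26	0.72
GAC	D	46	1.28
GAA	E	64	1.49
GAG	E	22	0.51
GGU	G	28	0.5
GGC	G	86	1.53
GGA	G	53	0.94
GGG	G	58	1.03
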