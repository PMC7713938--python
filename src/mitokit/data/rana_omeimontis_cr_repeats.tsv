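# Published tandem-repeat arrays of the Rana omeimontis control region, in
# "full_copies x period + partial" notation with the repeat unit sequence.
label	full_copies	period	partial	copy_number	unit
RU1	18	38	36	18.9	TCTATATGGATACTATCTCTATGTTTAATAATCATTAA
RU2	4	367	225	4.6	CCATATCATATTGTAGTATATGTCATGTCACACCATATTGTACCACATCATATTGTGCCATATTGTATCATGCCAGATCATTTCGTGTAATACCCCATCATATCATGTTATATCCCGCCACACCGTCTCGTATATTGCTACATCATACCCAGTCATATCAAATTGCATCCCACTTTCCCGTTCTAGATCGTATCGAATTTTATCGCGTCGTGTCATTATATACAGCACACACCCAATTAAAGTAGTTCTGCCCCCGACATGTCATGCTCACCACACTATAATTTTATTACCAGATGCCACATATCGCACATGTTAAATCATACTGCATTGTGTCATGTCACATAGCCTCGTACCATACCGTGTTGTA
RU3	1	30	27	1.9	CATGCGCACCTCCCTCATGCGCGCCTCCCT
RU4	3	15	4	3.3	CCTCCCTCATGCGCG
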