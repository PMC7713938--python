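# Published annotation of the Rana omeimontis mitogenome (GenBank MK483118; 20,120 bp circle).
# Coordinates are 1-based, fully closed intervals on the H strand.
name	class	start	end	strand	start_codon	stop_codon	intergenic_published
trnL2	tRNA	1	72	H			2
trnT	tRNA	75	144	H			0
trnP	tRNA	145	213	L			1
trnF	tRNA	215	284	H			0
12S	rRNA	285	1216	H			-1
trnV	tRNA	1216	1284	H			0
16S	rRNA	1285	2862	H			1
trnL1	tRNA	2864	2936	H			6
ND1	PCG	2940	3897	H	AAA	T--	0
trnI	tRNA	3898	3968	H			0
trnQ	tRNA	3969	4039	L			-1
trnM	tRNA	4039	4107	H			0
ND2	PCG	4108	5142	H	ATG	TAG	-2
trnW	tRNA	5141	5210	H			0
trnA	tRNA	5211	5280	L			0
trnN	tRNA	5281	5353	L			0
OL	OL	5354	5384	L			-3
trnC	tRNA	5382	5446	L			0
trnY	tRNA	5447	5513	L			4
COI	PCG	5518	7068	H	ATA	AGG	-9
trnS2	tRNA	7060	7130	L			1
trnD	tRNA	7132	7200	H			0
COII	PCG	7201	7888	H	ATG	T--	0
trnK	tRNA	7889	7957	H			1
ATP8	PCG	7959	8120	H	ATG	TAA	-23
ATP6	PCG	8114	8795	H	GTG	T--	0
COIII	PCG	8796	9579	H	ATG	T--	0
trnG	tRNA	9580	9647	H			0
ND3	PCG	9648	9987	H	ATG	T--	0
trnR	tRNA	9988	10057	H			0
ND4L	PCG	10058	10342	H	GTG	TAA	-7
ND4	PCG	10336	11695	H	ATG	T--	0
trnH	tRNA	11696	11764	H			0
trnS1	tRNA	11765	11831	H			30
ND5	PCG	11862	13649	H	ATG	AGA	0
NCR	NCR	13650	14200	H			0
ND6	PCG	14201	14695	L	ATG	AGA	0
trnE	tRNA	14696	14764	L			3
Cytb	PCG	14768	15910	H	ATG	TAA	0
CR	CR	15911	20120	H			0
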