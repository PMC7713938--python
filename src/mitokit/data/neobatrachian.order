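# Neobatrachian-type mitochondrial gene order (circular; anchored at trnF).
# "-" prefix marks L-strand tokens. 39 tokens: 13 PCGs, 22 tRNAs, 2 rRNAs, CR, OL.
trnF 12S trnV 16S trnL1 ND1 trnI -trnQ trnM ND2 trnW -trnA -trnN -OL -trnC -trnY COI -trnS2 trnD COII trnK ATP8 ATP6 COIII trnG ND3 trnR ND4L ND4 trnH trnS1 ND5 -ND6 -trnE Cytb CR trnL2 trnT trnP
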