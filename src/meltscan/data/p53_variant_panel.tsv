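context	label	seq_detected	hrm_detected	end_proximal
TGGCCCAGTA(T>A)TTTGAAGACC	Y186X	1	1	0
CCGCAGGTAA(A>T)GCTGCCCCAG	intron	0	1	0
CTACATGTGT(A>G)ACAGCTCGTG	N220D	1	0	0
TACATGTGTA(A>G)CAGCTCGTGC	N220S	1	1	0
GTGTAACAGC(T>C)CGTGCATGGG	S222P	1	1	0
GTGTAACAGCT(C>A)GTGCATGGG	S222X	0	1	0
TCTGGAAACC(G>T)AGTAAGTTTA	E241X	1	0	1
GGAAACCGAG(T>C)AAGTTTAGTC	splice	1	0	1
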