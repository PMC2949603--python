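gene	exons_screened	amplicons	bp_screened	stop	missense	silent	intron	splice
p53	2	1	1702800	2	2	0	1	0
ATM	5	4	7740932	1	14	3	9	0
ATR	7	4	7837612	1	10	6	6	0
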