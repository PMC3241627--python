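gene	betweenness	closeness
LGALS3	6.00	3.56
PECAM1	4.00	2.56
CD27	3.00	0.04
RECK	3.00	0.00
MGAT5	4.00	2.56
CLU	2.00	0.24
ITIH4	2.00	0.04
RBP4	1.00	0.12
APOD	1.00	0.00
CFB	1.00	0.00
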