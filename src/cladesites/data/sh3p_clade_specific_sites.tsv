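site	clade	domain	position	conserved_aa	aa_other_clades
1	SH3P3	BAR	32	E	G or gap
2	SH3P3	BAR	62	D or E	H or R
3	SH3P2	BAR	73	V or I	small hydrophilic (STA)
4	SH3P2	BAR	98	C	various
5	SH3P3	BAR	114	I or L	various
6	SH3P3	BAR	138	L or I	various
7	SH3P3	BAR	161	S	acid or amide (DEQ)
8	SH3P1	BAR	197	small hydrophilic (SAT)	various charged
9	SH3P1	BAR	248	K	various (mostly QDE)
10	SH3P3	BAR	265	K or R	various (mostly I)
11	SH3P2	linker	281	Y	various
12	SH3P3	linker	280	K	various (mostly NDE)
13	SH3P3	SH3	298	K	various
14	SH3P2	C-terminal	360	L	small hydrophilic (PAS)
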