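probe_id	gene_symbol	group
31711_at	GRIN2D	yin
34552_at	GAST	yin
35084_at	AMH	yin
32874_at	TCF3	yin
32975_g_at	EXOSC2	yin
33510_s_at	GRM1	yin
34027_f_at	HIST1H4J///HIST1H4K	yin
34510_at	CDT1	yin
37432_g_at	PIAS2	yin
39651_at	RECQL4	yin
40334_at	CSTF2	yin
41623_s_at	FZR1	yin
34664_at	FCGR2B	yin
35141_at	RNASEH2A	yin
36839_at	CDC6	yin
37267_at	THOP1	yin
41149_at	LOC81691	yin
33935_at	CACYBP	yin
34341_at	PPAT	yin
35800_at	PAFAH1B3	yin
39909_g_at	TAF6L	yin
40264_g_at	ZFPL1	yin
40532_at	BIRC5	yin
1738_at	CDC25A	yin
1601_s_at	IGFBP5	yin
1539_at	NRAS	yin
1133_at	EN2	yin
966_at	RAD54L	yin
895_at	MIF	yin
652_g_at	RPA3	yin
374_f_at	DDT///DDTL	yin
34174_s_at	LPHN2	yang
36377_at	IL18R1	yang
32904_at	PRF1	yang
34950_at	ZNF423	yang
37841_at	BCHE	yang
39209_r_at	PPBP	yang
39577_at	SOSTDC1	yang
39634_at	SLIT2	yang
40322_at	IL1RL1	yang
40398_s_at	MEOX2	yang
41030_at	FOXJ1	yang
34267_r_at	LEPR	yang
37194_at	GATA2	yang
37536_at	CD83	yang
38315_at	ALDH1A2	yang
39048_at	NOTCH4	yang
39085_at	TNNC1	yang
40763_at	MEIS1	yang
35828_at	CRIP2	yang
37710_at	MEF2C	yang
38734_at	PLN	yang
39544_at	SYNM	yang
40231_at	SMAD6	yang
40900_at	MYH10	yang
2039_s_at	FYN	yang
1733_at	BMP6	yang
1595_at	TEK	yang
873_at	HOXA5	yang
774_g_at	MYH11	yang
610_at	ADRB2	yang
560_s_at	TAL1	yang
481_at	SNRK	yang
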