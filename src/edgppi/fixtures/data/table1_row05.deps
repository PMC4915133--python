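# sent_id = table1_row05
1	Shc	shc	NN
2	,	,	,
3	which	which	WDT
4	specifically	specifically	RB
5	binds	bind	VBZ
6	the	the	DT
7	SH2	sh2	NN
8	domain	domain	NN
9	of	of	IN
10	GRB2	grb2	NN
11	.	.	.
punct(Shc-1, ,-2)
rcmod(Shc-1, binds-5)
nsubj(binds-5, which-3)
advmod(binds-5, specifically-4)
dobj(binds-5, domain-8)
det(domain-8, the-6)
nn(domain-8, SH2-7)
prep(domain-8, of-9)
pobj(of-9, GRB2-10)
punct(Shc-1, .-11)
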