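# sent_id = table1_row09
1	CD5	cd5	NN
2	is	be	VBZ
3	a	a	DT
4	T-cell-specific	t-cell-specific	JJ
5	antigen	antigen	NN
6	which	which	WDT
7	binds	bind	VBZ
8	to	to	TO
9	the	the	DT
10	B-cell	b-cell	NN
11	antigen	antigen	NN
12	CD72	cd72	NN
13	.	.	.
nsubj(antigen-5, CD5-1)
cop(antigen-5, is-2)
det(antigen-5, a-3)
amod(antigen-5, T-cell-specific-4)
rcmod(antigen-5, binds-7)
nsubj(binds-7, which-6)
prep(binds-7, to-8)
pobj(to-8, CD72-12)
det(CD72-12, the-9)
nn(CD72-12, B-cell-10)
nn(CD72-12, antigen-11)
punct(antigen-5, .-13)
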