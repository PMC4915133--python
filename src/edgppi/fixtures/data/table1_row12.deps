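# sent_id = table1_row12
1	ARTS	arts	NN
2	binds	bind	VBZ
3	to	to	TO
4	a	a	DT
5	distinct	distinct	JJ
6	domain	domain	NN
7	in	in	IN
8	XIAP-BIR3	xiap-bir3	NN
9	.	.	.
nsubj(binds-2, ARTS-1)
prep(binds-2, to-3)
pobj(to-3, domain-6)
det(domain-6, a-4)
amod(domain-6, distinct-5)
prep(domain-6, in-7)
pobj(in-7, XIAP-BIR3-8)
punct(binds-2, .-9)
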