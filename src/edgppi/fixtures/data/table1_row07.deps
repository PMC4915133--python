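# sent_id = table1_row07
1	p53	p53	NN
2	binds	bind	VBZ
3	and	and	CC
4	activates	activate	VBZ
5	the	the	DT
6	xeroderma	xeroderma	NN
7	pigmentosum	pigmentosum	NN
8	DDB2	ddb2	NN
9	gene	gene	NN
10	in	in	IN
11	humans	human	NNS
12	.	.	.
nsubj(binds-2, p53-1)
cc(binds-2, and-3)
conj(binds-2, activates-4)
dobj(activates-4, gene-9)
det(gene-9, the-5)
nn(gene-9, xeroderma-6)
nn(gene-9, pigmentosum-7)
nn(gene-9, DDB2-8)
prep(activates-4, in-10)
pobj(in-10, humans-11)
punct(binds-2, .-12)
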