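# sent_id = table1_row11
1	The	the	DT
2	basic	basic	JJ
3	cleft	cleft	NN
4	of	of	IN
5	RPA70N	rpa70n	NN
6	binds	bind	VBZ
7	multiple	multiple	JJ
8	checkpoint	checkpoint	NN
9	proteins	protein	NNS
10	,	,	,
11	including	including	VBG
12	RAD9	rad9	NN
13	.	.	.
nsubj(binds-6, cleft-3)
det(cleft-3, The-1)
amod(cleft-3, basic-2)
prep(cleft-3, of-4)
pobj(of-4, RPA70N-5)
dobj(binds-6, proteins-9)
amod(proteins-9, multiple-7)
nn(proteins-9, checkpoint-8)
punct(proteins-9, ,-10)
prep(proteins-9, including-11)
pobj(including-11, RAD9-12)
punct(binds-6, .-13)
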