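# sent_id = table1_row10
1	TPO	tpo	NN
2	binds	bind	VBZ
3	and	and	CC
4	activates	activate	VBZ
5	its	its	PRP$
6	receptor	receptor	NN
7	,	,	,
8	myeloproliferative	myeloproliferative	JJ
9	leukemia	leukemia	NN
10	virus	virus	NN
11	receptor	receptor	NN
12	.	.	.
nsubj(binds-2, TPO-1)
cc(binds-2, and-3)
conj(binds-2, activates-4)
dobj(binds-2, receptor-6)
poss(receptor-6, its-5)
punct(receptor-6, ,-7)
appos(receptor-6, receptor-11)
amod(receptor-11, myeloproliferative-8)
nn(receptor-11, leukemia-9)
nn(receptor-11, virus-10)
punct(binds-2, .-12)
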