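# sent_id = fig1_passive
1	IRF1	irf1	NN
2	is	be	VBZ
3	activated	activate	VBN
4	by	by	IN
5	STAT1	stat1	NN
6	.	.	.
nsubjpass(activated-3, IRF1-1)
auxpass(activated-3, is-2)
prep(activated-3, by-4)
pobj(by-4, STAT1-5)
punct(activated-3, .-6)
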