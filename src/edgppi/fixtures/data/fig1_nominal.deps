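# sent_id = fig1_nominal
1	Activation	activation	NN
2	of	of	IN
3	IRF1	irf1	NN
4	by	by	IN
5	STAT1	stat1	NN
6	.	.	.
prep(Activation-1, of-2)
pobj(of-2, IRF1-3)
prep(Activation-1, by-4)
pobj(by-4, STAT1-5)
punct(Activation-1, .-6)
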