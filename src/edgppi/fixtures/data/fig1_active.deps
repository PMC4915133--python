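# sent_id = fig1_active
1	STAT1	stat1	NN
2	activates	activate	VBZ
3	IRF1	irf1	NN
4	.	.	.
nsubj(activates-2, STAT1-1)
dobj(activates-2, IRF1-3)
punct(activates-2, .-4)
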