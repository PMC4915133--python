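# sent_id = table1_row01
1	HFE	hfe	NN
2	binds	bind	VBZ
3	to	to	TO
4	the	the	DT
5	transferrin	transferrin	NN
6	receptor	receptor	NN
7	.	.	.
nsubj(binds-2, HFE-1)
prep(binds-2, to-3)
pobj(to-3, receptor-6)
det(receptor-6, the-4)
nn(receptor-6, transferrin-5)
punct(binds-2, .-7)
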