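# sent_id = table1_row04
1	Raf-1	raf-1	NN
2	binding	bind	VBG
3	proteins	protein	NNS
4	,	,	,
5	Ras	ras	NN
6	.	.	.
nn(binding-2, Raf-1-1)
amod(proteins-3, binding-2)
punct(proteins-3, ,-4)
appos(proteins-3, Ras-5)
punct(proteins-3, .-6)
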