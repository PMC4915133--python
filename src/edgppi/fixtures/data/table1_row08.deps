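# sent_id = table1_row08
1	Histone	histone	NN
2	deacetylase	deacetylase	NN
3	1	1	CD
4	can	can	MD
5	repress	repress	VB
6	transcription	transcription	NN
7	by	by	IN
8	binding	bind	VBG
9	to	to	TO
10	Sp1	sp1	NN
11	.	.	.
nn(deacetylase-2, Histone-1)
num(deacetylase-2, 1-3)
nsubj(repress-5, deacetylase-2)
aux(repress-5, can-4)
dobj(repress-5, transcription-6)
prep(repress-5, by-7)
pcomp(by-7, binding-8)
prep(binding-8, to-9)
pobj(to-9, Sp1-10)
punct(repress-5, .-11)
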