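# sent_id = table1_row03
1	Binding	binding	NN
2	of	of	IN
3	G	g	NN
4	beta	beta	NN
5	gamma	gamma	NN
6	to	to	TO
7	Raf	raf	NN
8	.	.	.
prep(Binding-1, of-2)
pobj(of-2, gamma-5)
nn(gamma-5, G-3)
nn(gamma-5, beta-4)
prep(Binding-1, to-6)
pobj(to-6, Raf-7)
punct(Binding-1, .-8)
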