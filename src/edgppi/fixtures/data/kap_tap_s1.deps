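# sent_id = kap_tap_s1
1	Kap	kap	NN
2	β2B	β2b	NN
3	Is	be	VBZ
4	Associated	associate	VBN
5	with	with	IN
6	TAP	tap	NN
7	in	in	IN
8	the	the	DT
9	Presence	presence	NN
10	of	of	IN
11	RanGTP	rangtp	NN
nn(β2B-2, Kap-1)
nsubjpass(Associated-4, β2B-2)
auxpass(Associated-4, Is-3)
prep(Associated-4, with-5)
pobj(with-5, TAP-6)
prep(Associated-4, in-7)
pobj(in-7, Presence-9)
det(Presence-9, the-8)
prep(Presence-9, of-10)
pobj(of-10, RanGTP-11)
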