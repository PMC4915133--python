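# sent_id = kap_tap_s2
1	The	the	DT
2	data	datum	NNS
3	presented	present	VBN
4	support	support	VBP
5	the	the	DT
6	conclusion	conclusion	NN
7	that	that	IN
8	Kap	kap	NN
9	β2B	β2b	NN
10	is	be	VBZ
11	a	a	DT
12	major	major	JJ
13	carrier	carrier	NN
14	for	for	IN
15	export	export	NN
16	of	of	IN
17	cellular	cellular	JJ
18	mRNA	mrna	NN
19	and	and	CC
20	TAP	tap	NN
21	connects	connect	VBZ
22	Kap	kap	NN
23	β2B	β2b	NN
24	to	to	TO
25	the	the	DT
26	mRNAs	mrna	NNS
27	to	to	TO
28	be	be	VB
29	exported	export	VBN
30	,	,	,
31	whereas	whereas	IN
32	the	the	DT
33	direct	direct	JJ
34	interaction	interaction	NN
35	of	of	IN
36	TAP	tap	NN
37	with	with	IN
38	nucleoporins	nucleoporin	NNS
39	allows	allow	VBZ
40	lower	lower	JJR
41	rates	rate	NNS
42	of	of	IN
43	mRNA	mrna	NN
44	export	export	NN
45	.	.	.
det(data-2, The-1)
vmod(data-2, presented-3)
nsubj(support-4, data-2)
dobj(support-4, conclusion-6)
det(conclusion-6, the-5)
mark(carrier-13, that-7)
ccomp(conclusion-6, carrier-13)
nn(β2B-9, Kap-8)
nsubj(carrier-13, β2B-9)
cop(carrier-13, is-10)
det(carrier-13, a-11)
amod(carrier-13, major-12)
prep(carrier-13, for-14)
pobj(for-14, export-15)
prep(export-15, of-16)
pobj(of-16, mRNA-18)
amod(mRNA-18, cellular-17)
cc(carrier-13, and-19)
conj(carrier-13, connects-21)
nsubj(connects-21, TAP-20)
dobj(connects-21, β2B-23)
nn(β2B-23, Kap-22)
prep(connects-21, to-24)
pobj(to-24, mRNAs-26)
det(mRNAs-26, the-25)
vmod(mRNAs-26, exported-29)
aux(exported-29, to-27)
auxpass(exported-29, be-28)
punct(connects-21, ,-30)
mark(allows-39, whereas-31)
advcl(connects-21, allows-39)
nsubj(allows-39, interaction-34)
det(interaction-34, the-32)
amod(interaction-34, direct-33)
prep(interaction-34, of-35)
pobj(of-35, TAP-36)
prep(interaction-34, with-37)
pobj(with-37, nucleoporins-38)
dobj(allows-39, rates-41)
amod(rates-41, lower-40)
prep(rates-41, of-42)
pobj(of-42, export-44)
nn(export-44, mRNA-43)
punct(support-4, .-45)
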