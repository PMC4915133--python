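# sent_id = table1_row06
1	Structure	structure	NN
2	of	of	IN
3	ERK2	erk2	NN
4	bound	bind	VBN
5	to	to	TO
6	PEA-15	pea-15	NN
7	reveals	reveal	VBZ
8	a	a	DT
9	mechanism	mechanism	NN
10	for	for	IN
11	rapid	rapid	JJ
12	release	release	NN
13	of	of	IN
14	activated	activate	VBN
15	MAPK	mapk	NN
16	.	.	.
nsubj(reveals-7, Structure-1)
prep(Structure-1, of-2)
pobj(of-2, ERK2-3)
vmod(ERK2-3, bound-4)
prep(bound-4, to-5)
pobj(to-5, PEA-15-6)
dobj(reveals-7, mechanism-9)
det(mechanism-9, a-8)
prep(mechanism-9, for-10)
pobj(for-10, release-12)
amod(release-12, rapid-11)
prep(release-12, of-13)
pobj(of-13, MAPK-15)
amod(MAPK-15, activated-14)
punct(reveals-7, .-16)
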