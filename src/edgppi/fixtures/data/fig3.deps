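# sent_id = fig3
1	TR6	tr6	NN
2	specifically	specifically	RB
3	binds	bind	VBZ
4	two	two	CD
5	cellular	cellular	JJ
6	ligands	ligand	NNS
7	,	,	,
8	LIGHT	light	NN
9	(	-lrb-	-LRB-
10	herpes	herpes	NN
11	virus	virus	NN
12	entry	entry	NN
13	mediator	mediator	NN
14	(	-lrb-	-LRB-
15	HVEM	hvem	NN
16	)	-rrb-	-RRB-
17	-L	-l	NN
18	)	-rrb-	-RRB-
19	and	and	CC
20	Fas	fas	NN
21	ligand	ligand	NN
22	(	-lrb-	-LRB-
23	FasL/CD95L	fasl/cd95l	NN
24	)	-rrb-	-RRB-
25	.	.	.
nsubj(binds-3, TR6-1)
advmod(binds-3, specifically-2)
dobj(binds-3, ligands-6)
num(ligands-6, two-4)
amod(ligands-6, cellular-5)
punct(ligands-6, ,-7)
appos(ligands-6, LIGHT-8)
punct(LIGHT-8, LRB-9)
appos(LIGHT-8, L-17)
nn(L-17, herpes-10)
nn(L-17, virus-11)
nn(L-17, entry-12)
nn(L-17, mediator-13)
punct(L-17, LRB-14)
dep(L-17, HVEM-15)
punct(L-17, RRB-16)
punct(LIGHT-8, RRB-18)
cc(LIGHT-8, and-19)
conj(LIGHT-8, ligand-21)
nn(ligand-21, Fas-20)
punct(ligand-21, LRB-22)
appos(ligand-21, FasL-23)
punct(ligand-21, RRB-24)
punct(binds-3, .-25)
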