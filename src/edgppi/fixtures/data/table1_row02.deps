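# sent_id = table1_row02
1	Plasminogen	plasminogen	NN
2	activator	activator	NN
3	inhibitor	inhibitor	NN
4	1	1	CD
5	(	-lrb-	-LRB-
6	PAI	pai	NN
7	)	-rrb-	-RRB-
8	is	be	VBZ
9	bound	bind	VBN
10	to	to	TO
11	vitronectin	vitronectin	NN
12	in	in	IN
13	plasma	plasma	NN
14	.	.	.
nn(inhibitor-3, Plasminogen-1)
nn(inhibitor-3, activator-2)
num(inhibitor-3, 1-4)
punct(inhibitor-3, LRB-5)
dep(inhibitor-3, PAI-6)
punct(inhibitor-3, RRB-7)
nsubjpass(bound-9, inhibitor-3)
auxpass(bound-9, is-8)
prep(bound-9, to-10)
pobj(to-10, vitronectin-11)
prep(bound-9, in-12)
pobj(in-12, plasma-13)
punct(bound-9, .-14)
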