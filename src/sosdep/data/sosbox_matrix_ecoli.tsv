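#source=palindromically symmetrized count matrix from 14 experimentally characterized E. coli K-12 LexA operators (recA sulA umuDC uvrA uvrB uvrD lexA-op1 lexA-op2 recN dinI polB sbmC dinB ruvAB)
#length=20
#pseudocount=0.5
#n_sites=28
#core=3:C,4:T,5:G,16:C,17:A,18:G
pos	A	C	G	T
1	8	3	2	15
2	17	4	6	1
3	0	28	0	0
4	0	0	0	28
5	0	0	28	0
6	2	0	7	19
7	19	0	4	5
8	2	2	1	23
9	16	0	7	5
10	6	3	2	17
11	17	2	3	6
12	5	7	0	16
13	23	1	2	2
14	5	4	0	19
15	19	7	0	2
16	0	28	0	0
17	28	0	0	0
18	0	0	28	0
19	1	6	4	17
20	15	2	3	8
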