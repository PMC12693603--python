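# Functional-group SMARTS library for fragment attribution.
# Columns (tab-separated): priority  name  SMARTS
# Lower priority number = more specific group, matched first.
10	anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
11	carbamate	[NX3][CX3](=[OX1])[OX2]
12	amide	[CX3](=[OX1])[NX3]
13	ester	[CX3](=[OX1])[OX2H0][#6]
14	carboxylic acid	[CX3](=[OX1])[OX2H1]
15	aldehyde	[CX3H1]=[OX1]
16	ketone	[#6][CX3](=[OX1])[#6]
17	sulfone	[#16X4](=[OX1])(=[OX1])
18	sulfoxide	[#16X3]=[OX1]
19	nitro	[NX3](=[OX1])=[OX1]
20	nitrile	[NX1]#[CX2]
21	imine	[CX3]=[NX2]
22	phenol	[OX2H][c]
23	enol	[OX2H][CX3]=[CX3]
24	alcohol	[OX2H][CX4]
25	thiol	[SX2H]
26	thioether	[#16X2H0]([#6])[#6]
27	ether	[OX2H0]([#6])[#6]
28	primary amine	[NX3H2][#6]
29	secondary amine	[NX3H1]([#6])[#6]
30	tertiary amine	[NX3H0]([#6])([#6])[#6]
31	aromatic nitrogen	[nX2]
32	fluoro	[F][#6]
33	chloro	[Cl][#6]
34	bromo	[Br][#6]
35	phosphine	[PX3]
36	sodium alkoxide	[OX2][Na]
37	sodium	[Na]
38	carbonyl	[CX3]=[OX1]
40	benzene ring	c1ccccc1
41	aromatic 5-ring	[a]1[a][a][a][a]1
42	pyridine ring	n1ccccc1
43	furan ring	o1cccc1
44	thiophene ring	s1cccc1
50	cyclopropane	[C;R]1[C;R][C;R]1
51	cyclobutane	[C;R]1[C;R][C;R][C;R]1
52	cyclopentane	[C;R]1[C;R][C;R][C;R][C;R]1
53	cyclohexane	[C;R]1[C;R][C;R][C;R][C;R][C;R]1
60	alkyne	[CX2]#[CX2]
61	alkene	[CX3]=[CX3]
62	tert-butyl	[CX4]([CX4H3])([CX4H3])[CX4H3]
63	isopropyl	[CX4H1]([CX4H3])[CX4H3]
64	gem-dimethyl	[CX4]([CX4H3])[CX4H3]
70	quaternary carbon	[CX4H0]
71	methine group	[CX4H1]
72	methylene group	[CX4H2]
73	methyl group	[CX4H3]
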