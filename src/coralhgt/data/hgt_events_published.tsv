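no	ancestor	genes	protein_product	support	source
1	Coral	A.digitifera_2036	PNK3P	100	CA
2	Coral	A.digitifera_8849	SDR	100	CA
3	Coral	Seriatopora_31861	DEAD-like helicase	100	Bact
4	Coral	Seriatopora_16594	glyoxalase	100	CA
5	Coral	Seriatopora_17147	acyl-dehydrogenase	100	Bact
6	Coral	Seriatopora_17703	carbonic anhydrase	96	Dino
7	Coral	Seriatopora_19477	fatty acid or sphingolipid desaturase	100	CA
8	Coral	Seriatopora_3957	atpase domain-containing protein	100	Bact
9	Coral	Seriatopora_7060	sam domain-containing protein	100	Bact
10	Coral	Seriatopora_7928	atp phosphoribosyltransferase	100	CA/Fungi
11	Coral	Seriatopora_8296	glyoxalase	98	Bact
12	Coral	Seriatopora_22596	2-alkenal reductase	92	Bact
13	Coral	Seriatopora_28321	histidinol-phosphate aminotransferase	96	Unclear
14	Anthozoa	A.digitifera_418	duf718 domain protein	100	CA
15	Anthozoa	A.digitifera_15871	peptidase s49	96	Algae/Bact
16	Anthozoa	A.digitifera_14520	predicted protein	100	CA/Bact
17	Anthozoa	A.digitifera_7178	rok family protein/fructokinase	93	Red algae
18	Anthozoa	A.digitifera_10592	Phospholipid methyltransferase	100	CA/Viri
19	Anthozoa	A.digitifera_13390	predicted protein	100	Bact
20	Anthozoa	A.digitifera_313	malate synthase	98	CA/Bact
21	Anthozoa	A.digitifera_1537	hypothetical protein	100	Bact
22	Anthozoa	A.digitifera_13577	gamma-glutamyltranspeptidase 1-like	100	Unclear
23	Anthozoa	A.digitifera_5099	Isocitrate lyase (ICL)	100	Bact
24	Anthozoa	A.digitifera_13467	uncharacterized iron-regulated protein	100	CA
25	Anthozoa	A.digitifera_6866	3-dehydroquinate synthase	98	CA
26	Anthozoa	A.digitifera_11675	intein c-terminal splicing region protein	100	Bact
27	Anthozoa	Seriatopora_10994	penicillin amidase	100	Bact
28	Anthozoa	Seriatopora_14009	nucleoside phosphorylase-like protein	100	Bact
29	Anthozoa	Seriatopora_14494	phosphonoacetaldehyde hydrolase	100	Dino
30	Anthozoa	Seriatopora_15303	exonuclease-endonuclease-phosphatase	99	CA/Viri
31	Anthozoa	Seriatopora_15772	fmn-dependent nadh-azoreductase	99	Dino
32	Anthozoa	Seriatopora_19888	had family hydrolase	97	Algae/Bact
33	Anthozoa	Seriatopora_20039	chitodextrinase domain protein	92	Dino
34	Anthozoa	Seriatopora_20146	glutamate dehydrogenase	100	CA/Bact
35	Anthozoa	Seriatopora_20479	thif family protein	100	Bact
36	Anthozoa	Seriatopora_21195	ATP-dependent endonuclease	100	Dino
37	Anthozoa	Seriatopora_8585	chitodextrinase domain protein	92	Bact
38	Anthozoa	Seriatopora_24047	aminotransferase	100	Bact
39	Anthozoa	Seriatopora_25961	d-alanine ligase	99	Bact
40	Anthozoa	Seriatopora_26478	quercetin 3-o-methyltransferase	100	Viri
41	Anthozoa	Seriatopora_29443	diaminopimelate decarboxylase	100	CA
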