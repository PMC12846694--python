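breed	1-5	5-10	10-20	20-40	>40
YBHP	93	408	256	178	27
KENYA	25	122	52	10	0
USOS	9	85	58	7	1
USYU	21	149	81	23	0
CNBX	24	169	73	12	0
CNDH	46	215	115	37	2
CNEH	63	291	135	23	2
CNLT	50	297	162	29	5
CNMS	39	331	118	37	4
DEAS	22	165	78	21	0
DEBB	28	172	87	28	1
ESCM	42	248	129	19	2
ESIB	35	304	218	47	8
HUMA	38	236	137	33	1
ITMR	13	80	31	8	0
ITNS	11	126	62	14	2
SELI	13	105	65	18	3
PLPS	13	112	58	18	2
DUR	21	127	76	16	2
HS	28	189	138	29	3
LDR	27	168	141	34	5
LWT	18	154	122	27	4
PIET	22	160	86	35	5
PTBI	16	130	49	11	0
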