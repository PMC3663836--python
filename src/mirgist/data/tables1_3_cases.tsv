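case_id	age_class	sex	age	location	genotype	mutation	fish_14q32	sdhb_ihc	followup	risk	histology	carney_triad
1	adult	F	58	Stomach	KIT ex 11	Y553_W557del	Loss	NA	DOD	H	S	no
2	adult	F	37	Stomach	PDGFRA ex 18	D842V	Loss	NA	WD	L	S	no
3	adult	M	55	Stomach	PDGFRA ex 14	N659K	Loss	NA	WD	L	E	no
4	adult	F	73	Stomach	PDGFRA ex 18	D842V	Loss	NA	WD	L	E	no
5	adult	F	54	Stomach	KIT ex 11	M552_W557del	Loss	NA	WD	I	S&E	no
6	adult	M	44	Stomach	KIT ex 11	W557R	Loss	NA	WD	I	S&E	no
7	adult	F	78	Stomach	KIT ex 11	P551_E561delinsLQ	Diploid	NA	AWD	H	S	no
8	adult	F	65	Stomach	KIT ex 11	W557_V560delinsF	Loss	NA	AWD	H	E	no
9	adult	M	85	Stomach	KIT ex 11	V559A	Loss	NA	WD	L	S&E	no
10	adult	M	62	Stomach	PDGFRA ex 18	D842V	Loss	NA	WD	H	E	no
11	adult	M	44	Stomach	PDGFRA ex 18	D842V	Loss	NA	WD	I	S	no
12	adult	M	70	Stomach	KIT ex 11	W557_K558del	Loss	NA	AWD	H	E	no
13	adult	M	77	Stomach	KIT ex 11	V559D	Loss	NA	WD	L	E&S	no
14	adult	F	27	Stomach	KIT ex 11	556_573del	Loss	NA	AWD	I	S	no
15	adult	M	71	Stomach	KIT ex 11	V560_G565del	Loss	NA	AWD	H	S	no
16	adult	M	72	Stomach	PDGFRA ex 18	D842_M844del	Loss	NA	WD	I	E	no
17	adult	M	72	Stomach	KIT ex 11	K558_V559delinsN	Loss	NA	AWD	H	S	no
18	adult	M	62	Stomach	KIT ex 11	V554D	Loss	NA	WD	I	S	no
19	adult	M	67	Stomach	KIT ex 11	W557_K558del	Diploid	NA	DOD	H	S	no
20	adult	M	69	Stomach	PDGFRA ex 18	D842_I843del	Loss	NA	WD	I	S	no
21	adult	M	74	Stomach	KIT ex 11	V560D	Loss	NA	DOD	H	E	no
22	adult	F	48	Stomach	KIT ex 11	K550_V555del	Loss	NA	WD	H	S	no
23	adult	M	49	Stomach	PDGFRA ex 18	D842V	Trisomy	NA	WD	H	E	no
24	adult	M	68	Stomach	PDGFRA ex 12	V561D	Loss	NA	WD	I	E&S	no
25	adult	M	50	Stomach	PDGFRA ex 18	D842V	Loss	NA	WD	L	E	no
26	adult	F	71	Stomach	KIT ex 11	W557_K558del	Loss	NA	AWD	H	E	no
27	adult	F	46	Stomach	PDGFRA ex 18	D842V	Diploid	NA	WD	I	E	no
50	adult	F	58	Stomach	KIT ex 9	S476I	NA	positive	NA	NA	E&S	no
51	adult	F	22	Stomach	KIT ex 11	Y553_W557del	NA	positive	NA	NA	E	no
52	adult	M	58	Stomach	BRAF ex 15	V600E	Diploid	positive	NA	NA	E&S	no
28	adult	F	24	Stomach	WT	WT	NA	NA	NA	NA	E	no
29	adult	F	22	Stomach	WT	WT	NA	NA	NA	NA	E	no
30	adult	F	20	Stomach	WT	WT	NA	NA	NA	NA	E	no
32	adult	F	22	Stomach	WT	WT	NA	NA	NA	NA	E	no
35	adult	F	23	Stomach	WT	WT	NA	negative	NA	NA	E	no
36	adult	F	21	Stomach	WT	WT	Diploid	negative	NA	NA	E	no
38	adult	F	25	Stomach	WT	WT	Diploid	negative	NA	NA	E	no
46	adult	M	22	Stomach	WT	WT	NA	negative	NA	NA	E	no
48	adult	M	20	Stomach	WT	WT	NA	negative	NA	NA	E	no
49	adult	F	46	Stomach	WT	WT	NA	negative	NA	NA	NA	no
53	adult	F	20	Jejunum	WT	WT	Diploid	positive	NA	NA	E&S	no
54	adult	F	78	Stomach	WT	WT	NA	NA	NA	NA	E	no
55	adult	F	50	Stomach	WT	WT	NA	NA	NA	NA	E	no
56	adult	M	42	Stomach	WT	WT	NA	NA	NA	NA	S	no
60	adult	F	33	Stomach	WT	WT	NA	positive	NA	NA	S	no
63	adult	F	30	Jejunum	WT	WT	Diploid	positive	NA	NA	S	no
64	adult	F	40	Stomach	WT	WT	NA	negative	NA	NA	E	no
65	adult	F	28	Stomach	WT	WT	NA	negative	NA	NA	E	yes
66	adult	F	54	Ileum	WT	WT	Diploid	positive	NA	NA	S	no
68	adult	F	55	Stomach	WT	WT	NA	negative	NA	NA	E	no
69	adult	F	49	Stomach	WT	WT	NA	negative	NA	NA	E	no
70	adult	F	31	Stomach	WT	WT	NA	negative	NA	NA	E	no
71	adult	M	45	Ileum	WT	WT	Trisomy	positive	NA	NA	E	no
72	adult	F	46	Stomach	WT	WT	NA	positive	NA	NA	S	no
73	adult	M	37	Retroperitoneum	WT	WT	Diploid	positive	NA	NA	S	no
31	pediatric	F	15	Stomach	WT	WT	NA	NA	NA	NA	E	no
33	pediatric	M	13	Stomach	WT	WT	NA	NA	NA	NA	E	no
34	pediatric	F	14	Stomach	WT	WT	NA	NA	NA	NA	E	no
37	pediatric	M	14	Stomach	WT	WT	Diploid	negative	NA	NA	S&E	no
39	pediatric	F	10	Stomach	WT	WT	Diploid	negative	NA	NA	S&E	no
40	pediatric	F	17	Stomach	WT	WT	Diploid	negative	NA	NA	E	no
41	pediatric	M	14	Stomach	WT	WT	Diploid	negative	NA	NA	E	yes
42	pediatric	F	17	Stomach	WT	WT	Diploid	negative	NA	NA	E	yes
43	pediatric	F	10	Stomach	WT	WT	NA	NA	NA	NA	E	no
44	pediatric	F	16	Stomach	WT	WT	NA	NA	NA	NA	E	yes
45	pediatric	F	8	Stomach	WT	WT	NA	negative	NA	NA	E	no
47	pediatric	M	18	Stomach	WT	WT	NA	negative	NA	NA	E	no
57	pediatric	M	10	Stomach	WT	WT	NA	negative	NA	NA	E	no
58	pediatric	F	12	Stomach	WT	WT	NA	NA	NA	NA	NA	no
59	pediatric	F	11	Stomach	WT	WT	NA	negative	NA	NA	E	no
61	pediatric	M	18	Stomach	WT	WT	NA	NA	NA	NA	E	no
62	pediatric	F	19	Stomach	WT	WT	NA	negative	NA	NA	E	no
67	pediatric	F	18	Stomach	WT	WT	NA	negative	NA	NA	E	no
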