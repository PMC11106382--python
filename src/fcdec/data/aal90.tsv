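index	abbreviation	hemisphere
1	PreCG.L	L
2	PreCG.R	R
3	SFGdor.L	L
4	SFGdor.R	R
5	ORBsup.L	L
6	ORBsup.R	R
7	MFG.L	L
8	MFG.R	R
9	ORBmid.L	L
10	ORBmid.R	R
11	IFGoperc.L	L
12	IFGoperc.R	R
13	IFGtriang.L	L
14	IFGtriang.R	R
15	ORBinf.L	L
16	ORBinf.R	R
17	ROL.L	L
18	ROL.R	R
19	SMA.L	L
20	SMA.R	R
21	OLF.L	L
22	OLF.R	R
23	SFGmed.L	L
24	SFGmed.R	R
25	ORBsupmed.L	L
26	ORBsupmed.R	R
27	REC.L	L
28	REC.R	R
29	INS.L	L
30	INS.R	R
31	ACG.L	L
32	ACG.R	R
33	DCG.L	L
34	DCG.R	R
35	PCG.L	L
36	PCG.R	R
37	HIP.L	L
38	HIP.R	R
39	PHG.L	L
40	PHG.R	R
41	AMYG.L	L
42	AMYG.R	R
43	CAL.L	L
44	CAL.R	R
45	CUN.L	L
46	CUN.R	R
47	LING.L	L
48	LING.R	R
49	SOG.L	L
50	SOG.R	R
51	MOG.L	L
52	MOG.R	R
53	IOG.L	L
54	IOG.R	R
55	FFG.L	L
56	FFG.R	R
57	PoCG.L	L
58	PoCG.R	R
59	SPG.L	L
60	SPG.R	R
61	IPL.L	L
62	IPL.R	R
63	SMG.L	L
64	SMG.R	R
65	ANG.L	L
66	ANG.R	R
67	PCUN.L	L
68	PCUN.R	R
69	PCL.L	L
70	PCL.R	R
71	CAU.L	L
72	CAU.R	R
73	PUT.L	L
74	PUT.R	R
75	PAL.L	L
76	PAL.R	R
77	THA.L	L
78	THA.R	R
79	HES.L	L
80	HES.R	R
81	STG.L	L
82	STG.R	R
83	TPOsup.L	L
84	TPOsup.R	R
85	MTG.L	L
86	MTG.R	R
87	TPOmid.L	L
88	TPOmid.R	R
89	ITG.L	L
90	ITG.R	R
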