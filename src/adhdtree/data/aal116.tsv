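roi_id	name	hemisphere
1	Precentral gyrus	L
2	Precentral gyrus	R
3	Superior frontal gyrus, dorsolateral	L
4	Superior frontal gyrus, dorsolateral	R
5	Superior frontal gyrus, orbital part	L
6	Superior frontal gyrus, orbital part	R
7	Middle frontal gyrus	L
8	Middle frontal gyrus	R
9	Middle frontal gyrus, orbital part	L
10	Middle frontal gyrus, orbital part	R
11	Inferior frontal gyrus, opercular part	L
12	Inferior frontal gyrus, opercular part	R
13	Inferior frontal gyrus, triangular part	L
14	Inferior frontal gyrus, triangular part	R
15	Inferior frontal gyrus, orbital part	L
16	Inferior frontal gyrus, orbital part	R
17	Rolandic operculum	L
18	Rolandic operculum	R
19	Supplementary motor area	L
20	Supplementary motor area	R
21	Olfactory cortex	L
22	Olfactory cortex	R
23	Superior frontal gyrus, medial	L
24	Superior frontal gyrus, medial	R
25	Superior frontal gyrus, medial orbital	L
26	Superior frontal gyrus, medial orbital	R
27	Gyrus rectus	L
28	Gyrus rectus	R
29	Insula	L
30	Insula	R
31	Anterior cingulate and paracingulate gyri	L
32	Anterior cingulate and paracingulate gyri	R
33	Median cingulate and paracingulate gyri	L
34	Median cingulate and paracingulate gyri	R
35	Posterior cingulate gyrus	L
36	Posterior cingulate gyrus	R
37	Hippocampus	L
38	Hippocampus	R
39	Parahippocampal gyrus	L
40	Parahippocampal gyrus	R
41	Amygdala	L
42	Amygdala	R
43	Calcarine fissure and surrounding cortex	L
44	Calcarine fissure and surrounding cortex	R
45	Cuneus	L
46	Cuneus	R
47	Lingual gyrus	L
48	Lingual gyrus	R
49	Superior occipital gyrus	L
50	Superior occipital gyrus	R
51	Middle occipital gyrus	L
52	Middle occipital gyrus	R
53	Inferior occipital gyrus	L
54	Inferior occipital gyrus	R
55	Fusiform gyrus	L
56	Fusiform gyrus	R
57	Postcentral gyrus	L
58	Postcentral gyrus	R
59	Superior parietal gyrus	L
60	Superior parietal gyrus	R
61	Inferior parietal, but supramarginal and angular gyri	L
62	Inferior parietal, but supramarginal and angular gyri	R
63	Supramarginal gyrus	L
64	Supramarginal gyrus	R
65	Angular gyrus	L
66	Angular gyrus	R
67	Precuneus	L
68	Precuneus	R
69	Paracentral lobule	L
70	Paracentral lobule	R
71	Caudate nucleus	L
72	Caudate nucleus	R
73	Lenticular nucleus, putamen	L
74	Lenticular nucleus, putamen	R
75	Lenticular nucleus, pallidum	L
76	Lenticular nucleus, pallidum	R
77	Thalamus	L
78	Thalamus	R
79	Heschl gyrus	L
80	Heschl gyrus	R
81	Superior temporal gyrus	L
82	Superior temporal gyrus	R
83	Temporal pole: superior temporal gyrus	L
84	Temporal pole: superior temporal gyrus	R
85	Middle temporal gyrus	L
86	Middle temporal gyrus	R
87	Temporal pole: middle temporal gyrus	L
88	Temporal pole: middle temporal gyrus	R
89	Inferior temporal gyrus	L
90	Inferior temporal gyrus	R
91	Cerebellum, crus I	L
92	Cerebellum, crus I	R
93	Cerebellum, crus II	L
94	Cerebellum, crus II	R
95	Cerebellum, lobule III	L
96	Cerebellum, lobule III	R
97	Cerebellum, lobules IV-V	L
98	Cerebellum, lobules IV-V	R
99	Cerebellum, lobule VI	L
100	Cerebellum, lobule VI	R
101	Cerebellum, lobule VIIb	L
102	Cerebellum, lobule VIIb	R
103	Cerebellum, lobule VIII	L
104	Cerebellum, lobule VIII	R
105	Cerebellum, lobule IX	L
106	Cerebellum, lobule IX	R
107	Cerebellum, lobule X	L
108	Cerebellum, lobule X	R
109	Vermis, lobules I-II	L
110	Vermis, lobule III	R
111	Vermis, lobules IV-V	L
112	Vermis, lobule VI	R
113	Vermis, lobule VII	L
114	Vermis, lobule VIII	R
115	Vermis, lobule IX	L
116	Vermis, lobule X	R
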