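index	name	hemisphere	tissue_class
0	ctx-lh-bankssts	left	cortical
1	ctx-lh-caudalanteriorcingulate	left	cortical
2	ctx-lh-caudalmiddlefrontal	left	cortical
3	ctx-lh-cuneus	left	cortical
4	ctx-lh-entorhinal	left	cortical
5	ctx-lh-fusiform	left	cortical
6	ctx-lh-inferiorparietal	left	cortical
7	ctx-lh-inferiortemporal	left	cortical
8	ctx-lh-isthmuscingulate	left	cortical
9	ctx-lh-lateraloccipital	left	cortical
10	ctx-lh-lateralorbitofrontal	left	cortical
11	ctx-lh-lingual	left	cortical
12	ctx-lh-medialorbitofrontal	left	cortical
13	ctx-lh-middletemporal	left	cortical
14	ctx-lh-parahippocampal	left	cortical
15	ctx-lh-paracentral	left	cortical
16	ctx-lh-parsopercularis	left	cortical
17	ctx-lh-parsorbitalis	left	cortical
18	ctx-lh-parstriangularis	left	cortical
19	ctx-lh-pericalcarine	left	cortical
20	ctx-lh-postcentral	left	cortical
21	ctx-lh-posteriorcingulate	left	cortical
22	ctx-lh-precentral	left	cortical
23	ctx-lh-precuneus	left	cortical
24	ctx-lh-rostralanteriorcingulate	left	cortical
25	ctx-lh-rostralmiddlefrontal	left	cortical
26	ctx-lh-superiorfrontal	left	cortical
27	ctx-lh-superiorparietal	left	cortical
28	ctx-lh-superiortemporal	left	cortical
29	ctx-lh-supramarginal	left	cortical
30	ctx-lh-frontalpole	left	cortical
31	ctx-lh-temporalpole	left	cortical
32	ctx-lh-transversetemporal	left	cortical
33	ctx-lh-insula	left	cortical
34	Left-Thalamus-Proper	left	subcortical
35	Left-Caudate	left	subcortical
36	Left-Putamen	left	subcortical
37	Left-Pallidum	left	subcortical
38	Left-Hippocampus	left	subcortical
39	Left-Amygdala	left	subcortical
40	Left-Accumbens-area	left	subcortical
41	Left-Cerebellum-Cortex	left	subcortical
42	ctx-rh-bankssts	right	cortical
43	ctx-rh-caudalanteriorcingulate	right	cortical
44	ctx-rh-caudalmiddlefrontal	right	cortical
45	ctx-rh-cuneus	right	cortical
46	ctx-rh-entorhinal	right	cortical
47	ctx-rh-fusiform	right	cortical
48	ctx-rh-inferiorparietal	right	cortical
49	ctx-rh-inferiortemporal	right	cortical
50	ctx-rh-isthmuscingulate	right	cortical
51	ctx-rh-lateraloccipital	right	cortical
52	ctx-rh-lateralorbitofrontal	right	cortical
53	ctx-rh-lingual	right	cortical
54	ctx-rh-medialorbitofrontal	right	cortical
55	ctx-rh-middletemporal	right	cortical
56	ctx-rh-parahippocampal	right	cortical
57	ctx-rh-paracentral	right	cortical
58	ctx-rh-parsopercularis	right	cortical
59	ctx-rh-parsorbitalis	right	cortical
60	ctx-rh-parstriangularis	right	cortical
61	ctx-rh-pericalcarine	right	cortical
62	ctx-rh-postcentral	right	cortical
63	ctx-rh-posteriorcingulate	right	cortical
64	ctx-rh-precentral	right	cortical
65	ctx-rh-precuneus	right	cortical
66	ctx-rh-rostralanteriorcingulate	right	cortical
67	ctx-rh-rostralmiddlefrontal	right	cortical
68	ctx-rh-superiorfrontal	right	cortical
69	ctx-rh-superiorparietal	right	cortical
70	ctx-rh-superiortemporal	right	cortical
71	ctx-rh-supramarginal	right	cortical
72	ctx-rh-frontalpole	right	cortical
73	ctx-rh-temporalpole	right	cortical
74	ctx-rh-transversetemporal	right	cortical
75	ctx-rh-insula	right	cortical
76	Right-Thalamus-Proper	right	subcortical
77	Right-Caudate	right	subcortical
78	Right-Putamen	right	subcortical
79	Right-Pallidum	right	subcortical
80	Right-Hippocampus	right	subcortical
81	Right-Amygdala	right	subcortical
82	Right-Accumbens-area	right	subcortical
83	Right-Cerebellum-Cortex	right	subcortical
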