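patch_index,roi_label
0,precentral
1,precentral
2,precentral
3,paracentral
4,paracentral
5,postcentral
6,postcentral
7,postcentral
8,bankssts
9,caudalanteriorcingulate
10,caudalmiddlefrontal
11,cuneus
12,entorhinal
13,frontalpole
14,fusiform
15,inferiorparietal
16,inferiortemporal
17,insula
18,isthmuscingulate
19,lateraloccipital
20,lateralorbitofrontal
21,lingual
22,medialorbitofrontal
23,middletemporal
24,parahippocampal
25,parsopercularis
26,parsorbitalis
27,parstriangularis
28,pericalcarine
29,posteriorcingulate
30,precuneus
31,rostralanteriorcingulate
32,rostralmiddlefrontal
33,superiorfrontal
34,superiorparietal
35,superiortemporal
36,supramarginal
37,temporalpole
38,transversetemporal
39,bankssts
40,caudalanteriorcingulate
41,caudalmiddlefrontal
42,precentral
43,precentral
44,precentral
45,paracentral
46,paracentral
47,postcentral
48,postcentral
49,postcentral
50,bankssts
51,caudalanteriorcingulate
52,caudalmiddlefrontal
53,cuneus
54,entorhinal
55,frontalpole
56,fusiform
57,inferiorparietal
58,inferiortemporal
59,insula
60,isthmuscingulate
61,lateraloccipital
62,lateralorbitofrontal
63,lingual
64,medialorbitofrontal
65,middletemporal
66,parahippocampal
67,parsopercularis
68,parsorbitalis
69,parstriangularis
70,pericalcarine
71,posteriorcingulate
72,precuneus
73,rostralanteriorcingulate
74,rostralmiddlefrontal
75,superiorfrontal
76,superiorparietal
77,superiortemporal
78,supramarginal
79,temporalpole
80,transversetemporal
81,bankssts
82,caudalanteriorcingulate
83,caudalmiddlefrontal
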