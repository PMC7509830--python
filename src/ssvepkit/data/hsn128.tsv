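# 128-channel geodesic sensor-net layout (standard approximation).
# Columns: sensor_id  x  y  z  (unit sphere; +y nose, +z vertex)
sensor_id	x	y	z
1	0.688714	0.656964	-0.306710
2	0.618894	0.784651	0.035956
3	0.425106	0.839870	0.337496
4	0.312668	0.778794	0.543801
5	0.164431	0.632075	0.757260
6	0.000000	0.434488	0.900678
7	-0.141154	0.179800	0.973523
8	0.461635	0.874614	-0.148137
9	0.288333	0.950427	0.116418
10	0.193689	0.921307	0.337162
11	0.000000	0.844737	0.535181
12	-0.164431	0.632075	0.757260
13	-0.282369	0.377243	0.882018
14	0.132193	0.986312	-0.098556
15	0.000000	0.989407	0.145170
16	0.000000	0.946154	0.323718
17	0.000000	0.972709	-0.232028
18	-0.193689	0.921307	0.337162
19	-0.312668	0.778794	0.543801
20	-0.438315	0.586778	0.680861
21	-0.132193	0.986312	-0.098556
22	-0.288333	0.950427	0.116418
23	-0.425106	0.839870	0.337496
24	-0.514252	0.694354	0.503405
25	-0.461635	0.874614	-0.148137
26	-0.618894	0.784651	0.035956
27	-0.678822	0.651447	0.338848
28	-0.665487	0.498857	0.555219
29	-0.570753	0.323338	0.754780
30	-0.433229	0.112591	0.894224
31	-0.221883	-0.077666	0.971975
32	-0.688714	0.656964	-0.306710
33	-0.839447	0.541422	-0.046813
34	-0.871697	0.379188	0.310420
35	-0.790464	0.183618	0.584338
36	-0.650946	0.033853	0.758369
37	-0.443060	-0.172135	0.879811
38	-0.799114	0.440566	-0.409046
39	-0.985786	0.116526	-0.121028
40	-0.960422	0.004177	0.278519
41	-0.828383	-0.096089	0.551858
42	-0.678805	-0.266571	0.684225
43	-0.748069	0.277390	-0.602866
44	-0.875357	0.163599	-0.454956
45	-0.965522	-0.246679	-0.083165
46	-0.910896	-0.286326	0.297129
47	-0.794434	-0.355140	0.492697
48	-0.584375	0.219289	-0.781292
49	-0.719259	0.047581	-0.693110
50	-0.859682	-0.509982	-0.029430
51	-0.770992	-0.548678	0.323301
52	-0.657055	-0.506470	0.558361
53	-0.461288	-0.444073	0.768123
54	-0.247565	-0.372296	0.894487
55	0.000000	-0.236329	0.971673
56	-0.708538	-0.282056	-0.646853
57	-0.808570	-0.459497	-0.367529
58	-0.723620	-0.690170	0.006216
59	-0.591423	-0.731575	0.339143
60	-0.453306	-0.667425	0.590811
61	-0.253816	-0.593275	0.763938
62	0.000000	-0.718393	0.695638
63	-0.602083	-0.485689	-0.633721
64	-0.636762	-0.691696	-0.340721
65	-0.537821	-0.842924	0.015067
66	-0.399504	-0.848709	0.346540
67	-0.200339	-0.798731	0.567356
68	-0.415538	-0.702742	-0.577479
69	-0.399052	-0.859771	-0.318672
70	-0.303091	-0.952593	0.026489
71	-0.153381	-0.921122	0.357782
72	0.000000	-0.857991	0.513664
73	-0.207696	-0.806953	-0.552892
74	-0.126105	-0.947160	-0.294932
75	0.000000	-0.998532	0.054157
76	0.153381	-0.921122	0.357782
77	0.200339	-0.798731	0.567356
78	0.253816	-0.593275	0.763938
79	0.247565	-0.372296	0.894487
80	0.221883	-0.077666	0.971975
81	0.000000	-0.846370	-0.532596
82	0.126105	-0.947160	-0.294932
83	0.303091	-0.952593	0.026489
84	0.399504	-0.848709	0.346540
85	0.453306	-0.667425	0.590811
86	0.461288	-0.444073	0.768123
87	0.443060	-0.172135	0.879811
88	0.207696	-0.806953	-0.552892
89	0.399052	-0.859771	-0.318672
90	0.537821	-0.842924	0.015067
91	0.591423	-0.731575	0.339143
92	0.657055	-0.506470	0.558361
93	0.678805	-0.266571	0.684225
94	0.415538	-0.702742	-0.577479
95	0.636762	-0.691696	-0.340721
96	0.723620	-0.690170	0.006216
97	0.770992	-0.548678	0.323301
98	0.794434	-0.355140	0.492697
99	0.602083	-0.485689	-0.633721
100	0.808570	-0.459497	-0.367529
101	0.859682	-0.509982	-0.029430
102	0.910896	-0.286326	0.297129
103	0.828383	-0.096089	0.551858
104	0.650946	0.033853	0.758369
105	0.433229	0.112591	0.894224
106	0.141154	0.179800	0.973523
107	0.708538	-0.282056	-0.646853
108	0.965522	-0.246679	-0.083165
109	0.960422	0.004177	0.278519
110	0.790464	0.183618	0.584338
111	0.570753	0.323338	0.754780
112	0.282369	0.377243	0.882018
113	0.719259	0.047581	-0.693110
114	0.875357	0.163599	-0.454956
115	0.985786	0.116526	-0.121028
116	0.871697	0.379188	0.310420
117	0.665487	0.498857	0.555219
118	0.438315	0.586778	0.680861
119	0.584375	0.219289	-0.781292
120	0.748069	0.277390	-0.602866
121	0.799114	0.440566	-0.409046
122	0.839447	0.541422	-0.046813
123	0.678822	0.651447	0.338848
124	0.514252	0.694354	0.503405
125	0.695721	0.514403	-0.501361
126	0.372733	0.662047	-0.650203
127	-0.372733	0.662047	-0.650203
128	-0.695721	0.514403	-0.501361
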