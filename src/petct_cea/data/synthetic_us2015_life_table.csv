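age,q_annual
0,0.000600
1,0.000600
2,0.000600
3,0.000600
4,0.000600
5,0.000600
6,0.000600
7,0.000600
8,0.000600
9,0.000600
10,0.000600
11,0.000600
12,0.000600
13,0.000600
14,0.000600
15,0.000600
16,0.000600
17,0.000600
18,0.000600
19,0.000600
20,0.000600
21,0.000600
22,0.000600
23,0.000600
24,0.000600
25,0.000600
26,0.000600
27,0.000600
28,0.000600
29,0.000600
30,0.000611
31,0.000667
32,0.000727
33,0.000794
34,0.000866
35,0.000945
36,0.001031
37,0.001125
38,0.001228
39,0.001340
40,0.001462
41,0.001596
42,0.001741
43,0.001900
44,0.002073
45,0.002262
46,0.002469
47,0.002694
48,0.002939
49,0.003207
50,0.003500
51,0.003819
52,0.004168
53,0.004548
54,0.004962
55,0.005415
56,0.005909
57,0.006448
58,0.007036
59,0.007678
60,0.008378
61,0.009142
62,0.009976
63,0.010885
64,0.011878
65,0.012961
66,0.014144
67,0.015434
68,0.016841
69,0.018377
70,0.020053
71,0.021882
72,0.023878
73,0.026056
74,0.028432
75,0.031025
76,0.033855
77,0.036942
78,0.040312
79,0.043988
80,0.048000
81,0.052378
82,0.057155
83,0.062368
84,0.068056
85,0.074263
86,0.081036
87,0.088426
88,0.096491
89,0.105291
90,0.114894
91,0.125373
92,0.136808
93,0.149285
94,0.162900
95,0.177757
96,0.193970
97,0.211660
98,0.230964
99,0.252029
100,0.275015
101,0.300098
102,0.327468
103,0.357334
104,0.389924
105,0.425486
106,0.464292
107,0.506637
108,0.552844
109,0.603266
110,0.658286
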