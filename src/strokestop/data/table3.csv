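patient_id,group,psv_cm_s,edv_cm_s,sdvr,lp_pla2,lp_pla2_unit,plaque,stenosis_pct,hpx,il4,printed_index
1,,,,,252.9,ug/l,echogenic,70,,,58
2,,,,,256.1,ug/l,echogenic,70,,,59
3,,,,,265.9,ug/l,echogenic,70,,,62
4,,,,,261.1,ug/l,echogenic,75,,,64
5,,,,,268.2,ug/l,echogenic,80,,,68
6,,,,,279.8,ug/l,echogenic,75,,,69
7,,,,,257.3,ug/l,echogenic,80,,,73
8,,,,,261.3,ug/l,echogenic,80,,,78
9,,,,,253.8,ug/l,echogenic,85,,,79
10,,,,,266.5,ug/l,echogenic,85,,,79
11,,,,,253.6,ug/l,echogenic,85,,,82
12,,,,,263.5,ug/l,echogenic,85,,,83
13,,,,,252.8,ug/l,echogenic,85,,,83
14,,,,,253.9,ug/l,echogenic,89,,,86
15,,,,,254.7,ug/l,echogenic,87,,,86
16,,,,,256.6,ug/l,echogenic,90,,,87
17,,,,,263.8,ug/l,echogenic,87,,,89
18,,,,,254.7,ug/l,heterogeneous,70,,,89
19,,,,,252.7,ug/l,echogenic,90,,,91
20,,,,,253.4,ug/l,echogenic,90,,,92
21,,,,,267.1,ug/l,echogenic,90,,,93
22,,,,,264.9,ug/l,heterogeneous,75,,,98
23,,,,,267.1,ug/l,echogenic,70,,,102
24,,,,,276.1,ug/l,heterogeneous,65,,,102
25,,,,,274.1,ug/l,heterogeneous,50,,,107
26,,,,,285.9,ug/l,heterogeneous,60,,,107
27,,,,,264.7,ug/l,heterogeneous,85,,,111
28,,,,,266.7,ug/l,heterogeneous,80,,,112
29,,,,,288.9,ug/l,heterogeneous,70,,,112
30,,,,,256.8,ug/l,heterogeneous,85,,,115
31,,,,,285.3,ug/l,echolucent,55,,,115
32,,,,,285.1,ug/l,heterogeneous,80,,,117
33,,,,,286.1,ug/l,heterogeneous,50,,,117
34,,,,,263.5,ug/l,heterogeneous,90,,,118
35,,,,,263.5,ug/l,heterogeneous,85,,,118
36,,,,,266.5,ug/l,heterogeneous,90,,,119
37,,,,,253.9,ug/l,heterogeneous,90,,,119
38,,,,,290.1,ug/l,echolucent,75,,,123
39,,,,,284.7,ug/l,heterogeneous,95,,,125
40,,,,,315.3,ug/l,heterogeneous,70,,,126
41,,,,,286.3,ug/l,echolucent,70,,,127
42,,,,,285.7,ug/l,heterogeneous,90,,,127
43,,,,,296.9,ug/l,heterogeneous,70,,,129
44,,,,,275.7,ug/l,heterogeneous,90,,,132
45,,,,,285.7,ug/l,heterogeneous,90,,,136
46,,,,,274.2,ug/l,heterogeneous,85,,,137
47,,,,,285.6,ug/l,heterogeneous,95,,,137
48,,,,,286.3,ug/l,heterogeneous,90,,,139
49,,,,,285.9,ug/l,heterogeneous,90,,,139
50,,,,,284.9,ug/l,heterogeneous,95,,,142
51,,,,,285.2,ug/l,heterogeneous,95,,,143
52,,,,,295.7,ug/l,heterogeneous,80,,,148
53,,,,,295.5,ug/l,heterogeneous,95,,,157
54,,,,,300.1,ug/l,echolucent,60,,,164
55,,,,,300.9,ug/l,echolucent,85,,,210
56,,,,,299.9,ug/l,echolucent,90,,,216
57,,,,,297.8,ug/l,echolucent,75,,,219
58,,,,,328.6,ug/l,echolucent,75,,,229
59,,,,,287.1,ug/l,echolucent,85,,,238
60,,,,,299.9,ug/l,echolucent,80,,,239
61,,,,,287.9,ug/l,echolucent,85,,,259
62,,,,,289.5,ug/l,echolucent,90,,,260
63,,,,,298.9,ug/l,echolucent,80,,,268
64,,,,,300.7,ug/l,echolucent,85,,,270
65,,,,,286.2,ug/l,echolucent,95,,,278
66,,,,,301.2,ug/l,echolucent,90,,,279
67,,,,,298.4,ug/l,echolucent,90,,,284
68,,,,,304.7,ug/l,echolucent,90,,,285
69,,,,,304.4,ug/l,echolucent,95,,,292
70,,,,,301.6,ug/l,echolucent,90,,,293
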