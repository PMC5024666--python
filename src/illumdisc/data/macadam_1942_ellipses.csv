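index,x,y,a_1e3,b_1e3,theta_deg
1,0.160,0.057,0.85,0.35,62.5
2,0.187,0.118,2.20,0.55,77.0
3,0.253,0.125,2.50,1.30,55.5
4,0.150,0.680,9.60,2.30,105.0
5,0.131,0.521,4.70,2.00,112.5
6,0.212,0.550,5.80,2.30,100.0
7,0.258,0.450,5.00,2.00,92.0
8,0.152,0.365,3.80,1.90,110.0
9,0.280,0.385,4.00,1.50,75.5
10,0.380,0.498,4.40,1.20,70.0
11,0.160,0.200,2.10,0.95,104.0
12,0.228,0.250,3.10,0.90,72.0
13,0.305,0.323,2.30,0.90,58.0
14,0.385,0.393,3.80,1.60,65.5
15,0.472,0.399,3.20,1.40,51.0
16,0.527,0.350,2.60,1.30,20.0
17,0.475,0.300,2.90,1.10,28.5
18,0.510,0.236,2.40,1.20,29.5
19,0.596,0.283,2.60,1.30,13.0
20,0.344,0.284,2.30,0.90,60.0
21,0.390,0.237,2.50,1.00,47.0
22,0.441,0.198,2.80,0.95,34.5
23,0.278,0.223,2.40,0.55,57.5
24,0.300,0.163,2.90,0.60,54.0
25,0.365,0.153,3.60,0.95,40.0
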