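wavelength_nm,L,M,S
400,0.0024,0.0028,0.0621
410,0.0092,0.0111,0.2312
420,0.0275,0.0365,0.5684
430,0.0611,0.0897,0.9010
440,0.1060,0.1568,0.9920
450,0.1526,0.2385,0.8702
460,0.2130,0.3345,0.5880
470,0.3086,0.4635,0.3804
480,0.4036,0.5710,0.2150
490,0.4977,0.6873,0.1127
500,0.5770,0.6850,0.0587
510,0.6980,0.8250,0.0297
520,0.8020,0.9310,0.0144
530,0.8840,0.9870,0.0069
540,0.9430,1.0000,0.0033
550,0.9810,0.9650,0.0016
560,0.9990,0.8890,0.0008
570,0.9960,0.7770,0.0004
580,0.9560,0.6370,0.0002
590,0.8910,0.4880,0.0001
600,0.7990,0.3470,0.0000
610,0.6850,0.2260,0.0000
620,0.5570,0.1360,0.0000
630,0.4260,0.0760,0.0000
640,0.3070,0.0400,0.0000
650,0.2060,0.0200,0.0000
660,0.1290,0.0098,0.0000
670,0.0760,0.0046,0.0000
680,0.0430,0.0022,0.0000
690,0.0230,0.0010,0.0000
700,0.0120,0.0005,0.0000
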