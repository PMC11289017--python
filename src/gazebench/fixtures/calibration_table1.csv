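participant,eyelink_mean_deg,eyelink_max_deg,webcam_mean_deg
1,0.64,1.45,1.38
2,0.35,0.55,0.96
3,0.44,1.13,1.44
4,0.61,0.93,1.37
5,0.39,0.85,1.21
6,0.58,1.52,1.74
7,0.45,0.90,1.09
8,0.59,0.86,1.17
9,0.50,1.38,1.46
10,0.48,1.42,1.59
11,0.42,1.10,1.92
12,0.49,0.95,0.97
13,0.46,0.97,1.77
14,0.55,0.95,1.31
15,0.47,0.67,2.60
16,0.51,0.98,1.20
17,0.63,1.24,1.33
18,0.52,1.28,1.10
19,0.50,0.80,1.76
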