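sample_no,glucose_mg_dl
1,86
2,89
3,92
4,93
5,96
6,105
7,113
8,125
9,135
10,137
11,146
12,177
13,198
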