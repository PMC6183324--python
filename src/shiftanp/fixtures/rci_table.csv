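n,rci
1,0
2,0
3,0.52
4,0.89
5,1.11
6,1.25
7,1.35
8,1.40
9,1.45
10,1.49
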