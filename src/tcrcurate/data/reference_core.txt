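# IMGT position, canonical-frame coordinates (A)
3 10.5082 9.0000 2.7057
4 7.2300 9.0000 -5.8091
5 4.6307 9.0000 3.9116
6 1.2821 9.0000 -4.9461
19 -1.2469 9.0000 5.1175
20 -4.6658 9.0000 -4.0831
21 -7.1245 9.0000 6.3234
22 -10.6137 9.0000 -3.2200
23 10.5082 3.0000 2.7057
24 7.2300 3.0000 -5.8091
25 4.6307 3.0000 3.9116
26 1.2821 3.0000 -4.9461
39 -1.2469 3.0000 5.1175
40 -4.6658 3.0000 -4.0831
41 -7.1245 3.0000 6.3234
42 -10.6137 3.0000 -3.2200
66 10.5082 -3.0000 2.7057
67 7.2300 -3.0000 -5.8091
68 4.6307 -3.0000 3.9116
69 1.2821 -3.0000 -4.9461
70 -1.2469 -3.0000 5.1175
71 -4.6658 -3.0000 -4.0831
89 -7.1245 -3.0000 6.3234
90 -10.6137 -3.0000 -3.2200
91 10.5082 -9.0000 2.7057
92 7.2300 -9.0000 -5.8091
101 4.6307 -9.0000 3.9116
102 1.2821 -9.0000 -4.9461
103 -1.2469 -9.0000 5.1175
104 -4.6658 -9.0000 -4.0831
118 -7.1245 -9.0000 6.3234
119 -10.6137 -9.0000 -3.2200
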