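ltc	n_terms
17	1
16	1
15	1
14	1
13	1
12	1
11	4
10	11
9	28
8	15
7	24
6	38
5	69
4	111
3	195
2	452
1	2169
0	52254
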