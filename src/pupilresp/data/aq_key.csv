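item,keyed_direction
1,disagree
2,agree
3,disagree
4,agree
5,agree
6,agree
7,agree
8,disagree
9,agree
10,disagree
11,disagree
12,agree
13,agree
14,disagree
15,disagree
16,agree
17,disagree
18,agree
19,agree
20,agree
21,agree
22,agree
23,agree
24,disagree
25,disagree
26,agree
27,disagree
28,disagree
29,disagree
30,disagree
31,disagree
32,disagree
33,agree
34,disagree
35,agree
36,disagree
37,disagree
38,disagree
39,agree
40,disagree
41,agree
42,agree
43,agree
44,disagree
45,agree
46,agree
47,disagree
48,disagree
49,disagree
50,disagree
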