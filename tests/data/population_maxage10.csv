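age,sex,count
0,F,46
1,F,45
2,F,46
3,F,46
4,F,46
5,F,46
6,F,46
7,F,46
8,F,46
9,F,45
10,F,45
0,M,45
1,M,45
2,M,46
3,M,46
4,M,46
5,M,45
6,M,45
7,M,45
8,M,46
9,M,45
10,M,45
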