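age,sex,q_all_cause
0,F,2.9999550004489173e-05
1,F,3.2989221497414789e-05
2,F,3.6276829909587249e-05
3,F,3.9892065134106147e-05
4,F,4.3867575472811282e-05
5,F,4.8239262373961367e-05
6,F,5.3046604522100083e-05
7,F,5.8333014203659772e-05
8,F,6.4146229157624468e-05
9,F,7.0538743443093743e-05
10,F,1
0,M,4.499898751519904e-05
1,M,4.9483424135687848e-05
2,M,5.4414751358256019e-05
3,M,5.9837500930748355e-05
4,M,6.5800641567359541e-05
5,M,7.2358020918983357e-05
6,M,7.9568851545475106e-05
7,M,8.7498245265438257e-05
8,M,9.6217800692799393e-05
9,M,0.00010580624924982907
10,M,1
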