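replicate,passage,fraction_r
0,0,0.902
0,1,0.8713
0,2,0.8476
0,3,0.815
0,4,0.7722
0,5,0.7322
0,6,0.6521
0,7,0.5878
0,8,0.4934
0,9,0.4035
0,10,0.2898
0,11,0.1778
0,12,0.094
0,13,0.0547
0,14,0.0235
0,15,0.0138
0,16,0.0069
0,17,0.0021
0,18,0.0015
0,19,0.0008
0,20,0.0003
0,21,0.0
0,22,0.0
0,23,0.0
0,24,0.0
0,25,0.0
0,26,0.0
0,27,0.0
0,28,0.0
0,29,0.0
0,30,0.0
1,0,0.9049
1,1,0.8851
1,2,0.8723
1,3,0.8534
1,4,0.8222
1,5,0.797
1,6,0.7471
1,7,0.6971
1,8,0.6222
1,9,0.5281
1,10,0.4142
1,11,0.3038
1,12,0.2006
1,13,0.1115
1,14,0.0511
1,15,0.0255
1,16,0.0166
1,17,0.0053
1,18,0.0028
1,19,0.0011
1,20,0.0001
1,21,0.0
1,22,0.0
1,23,0.0
1,24,0.0
1,25,0.0
1,26,0.0
1,27,0.0
1,28,0.0
1,29,0.0
1,30,0.0
2,0,0.9002
2,1,0.8844
2,2,0.8758
2,3,0.8569
2,4,0.8173
2,5,0.7871
2,6,0.7336
2,7,0.6768
2,8,0.5917
2,9,0.5085
2,10,0.4147
2,11,0.3001
2,12,0.213
2,13,0.12
2,14,0.061
2,15,0.0291
2,16,0.0123
2,17,0.0043
2,18,0.0015
2,19,0.0011
2,20,0.0005
2,21,0.0
2,22,0.0
2,23,0.0
2,24,0.0
2,25,0.0
2,26,0.0
2,27,0.0
2,28,0.0
2,29,0.0
2,30,0.0
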