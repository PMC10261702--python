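true_cat,samp,c1_1210,c1_1310,c1_1700,c1_all,c2_1210,c2_1310,c2_1700,c2_all,c3_1210,c3_1310,c3_1700,c3_all
1,1,2,3,3,1,1,1,1,1,3,2,3,3
1,2,1,1,1,1,1,1,1,1,1,2,1,1
1,3,1,1,1,1,1,1,1,1,1,1,1,1
1,4,3,2,1,1,1,2,1,1,1,1,1,1
2,5,2,1,2,2,2,1,2,2,2,2,2,2
2,6,2,3,2,2,2,2,2,2,2,2,2,2
2,7,3,2,2,2,2,2,2,2,3,1,3,2
2,8,2,2,2,2,3,1,2,3,2,2,2,2
2,9,2,2,2,2,1,2,2,2,2,2,2,2
3,10,1,2,3,3,3,1,2,1,2,3,3,3
3,11,3,3,3,3,3,3,3,3,3,3,1,3
3,12,3,3,3,3,3,2,3,3,3,3,3,3
3,13,2,3,3,3,1,2,3,3,3,3,3,3
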