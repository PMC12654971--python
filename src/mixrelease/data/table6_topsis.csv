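scheme,d_plus,d_minus,closeness,rank
45,0.009,0.129,0.932,1
29,0.013,0.128,0.908,2
15,0.014,0.123,0.901,3
44,0.014,0.125,0.898,4
43,0.022,0.117,0.839,5
40,0.023,0.115,0.834,6
42,0.023,0.115,0.831,7
38,0.024,0.113,0.823,8
41,0.025,0.114,0.819,9
30,0.028,0.118,0.809,10
39,0.029,0.109,0.790,11
26,0.030,0.109,0.782,12
28,0.035,0.102,0.747,13
14,0.038,0.101,0.728,14
37,0.038,0.098,0.720,15
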