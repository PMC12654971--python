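row,X1,X2,X3,X4,X5,Y_2,Y_8,Y_24
baseline,40.000,10.000,5.000,15.000,12.800,20.900,59.500,91.500
scheme_45,38.422,13.513,6.275,17.068,7.523,22.747,64.983,100.227
change,-1.578,3.513,1.275,2.068,-5.277,1.847,5.483,8.727
rate_pct,-3.945,35.130,25.500,13.787,-41.227,8.837,9.215,9.538
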