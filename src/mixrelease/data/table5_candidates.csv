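algorithm,scheme,X1,X2,X3,X4,X5,Y_2,Y_8,Y_24
NSGA-III,1,36.786,11.010,9.126,19.382,6.497,18.421,61.084,97.463
NSGA-III,2,33.465,20.442,2.953,20.694,5.247,19.610,61.360,95.307
NSGA-III,3,25.217,23.427,7.792,15.251,11.115,19.378,61.829,97.645
NSGA-III,4,30.039,21.690,3.386,20.997,6.690,20.154,61.965,96.071
NSGA-III,5,30.066,15.112,2.690,22.218,12.714,20.332,62.021,95.805
NSGA-III,6,25.199,18.156,6.158,21.725,11.563,20.638,62.845,98.010
NSGA-III,7,31.293,15.830,7.244,22.492,5.941,20.606,62.991,98.630
NSGA-III,8,27.350,17.315,9.844,20.670,7.622,20.312,63.078,99.733
NSGA-III,9,28.589,15.035,5.915,21.651,11.612,20.912,63.083,98.152
NSGA-III,10,34.957,12.257,4.536,20.992,10.060,21.492,63.463,97.999
NSGA-III,11,27.365,20.745,8.401,15.921,10.370,21.092,63.636,99.698
NSGA-III,12,31.423,18.737,4.185,16.744,11.714,22.102,64.016,98.399
NSGA-III,13,34.848,16.477,3.089,16.782,11.606,22.268,64.020,97.970
NSGA-III,14,26.544,22.193,4.914,20.584,8.566,22.127,64.159,98.856
NSGA-III,15,30.737,17.228,6.657,20.785,7.396,22.456,64.749,100.145
MOGWO,16,25.000,27.800,10.000,15.000,5.000,18.685,61.481,98.218
MOGWO,17,26.845,16.251,9.996,22.169,7.539,18.940,61.729,98.444
MOGWO,18,37.269,18.310,2.990,19.033,5.198,20.144,61.900,95.862
MOGWO,19,35.501,17.066,2.656,20.937,6.642,20.396,62.098,95.916
MOGWO,20,25.437,21.107,8.909,21.144,6.204,20.406,63.039,99.339
MOGWO,21,30.350,25.226,3.143,16.339,7.743,20.871,62.643,96.645
MOGWO,22,45.380,12.056,2.000,15.000,8.364,21.171,62.771,96.316
MOGWO,23,42.505,11.207,2.000,15.241,11.847,21.210,62.799,96.317
MOGWO,24,43.351,13.841,3.193,16.317,6.099,21.309,63.092,97.127
MOGWO,25,41.335,17.011,2.685,15.009,6.761,21.458,63.164,96.993
MOGWO,26,33.684,13.244,8.600,18.226,9.046,21.465,64.042,100.193
MOGWO,27,27.207,23.936,5.577,19.627,6.453,21.618,63.754,98.729
MOGWO,28,37.560,19.496,5.629,15.115,5.001,21.994,64.142,99.149
MOGWO,29,34.682,19.649,8.314,15.000,5.156,22.160,64.703,100.765
MOGWO,30,37.852,14.293,3.695,15.123,11.838,23.019,64.860,99.049
NSWOA,31,36.758,12.245,3.426,21.961,8.411,21.083,62.894,97.004
NSWOA,32,37.177,14.354,5.786,16.485,9.004,21.186,63.346,98.384
NSWOA,33,37.834,13.160,5.379,16.507,9.925,21.352,63.448,98.318
NSWOA,34,37.957,13.310,5.828,16.589,9.121,21.475,63.640,98.694
NSWOA,35,37.477,12.039,5.400,19.884,8.001,21.579,63.684,98.578
NSWOA,36,37.765,13.067,5.553,16.845,9.574,21.797,63.920,98.862
NSWOA,37,37.337,13.923,5.741,16.795,9.008,21.858,64.011,99.031
NSWOA,38,38.468,12.654,5.799,16.442,9.440,22.337,64.497,99.537
NSWOA,39,38.084,15.617,5.117,16.204,7.782,22.371,64.435,99.218
NSWOA,40,37.991,13.178,5.806,16.710,9.119,22.384,64.546,99.591
NSWOA,41,39.069,12.346,5.239,16.276,9.873,22.492,64.568,99.383
NSWOA,42,38.803,12.318,5.419,16.442,9.821,22.498,64.600,99.487
NSWOA,43,39.331,12.360,5.208,16.550,9.352,22.607,64.679,99.486
NSWOA,44,38.198,13.213,5.766,16.474,9.152,22.741,64.898,99.927
NSWOA,45,38.422,13.513,6.275,17.068,7.523,22.747,64.983,100.227
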