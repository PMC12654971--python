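formulation,X1,X2,X3,X4,X5,Y_2,Y_8,Y_24
1,29.5,22.6,7.2,16.4,7.1,17.1,64.4,98.1
2,25.2,27.8,2.0,22.8,5.0,17.5,54.4,87.3
3,41.4,10.0,10.0,16.4,5.0,16.0,59.8,102.3
4,38.3,14.4,4.5,17.8,7.8,19.3,61.2,93.2
5,32.5,17.5,5.0,22.8,5.0,17.7,58.8,92.5
6,29.0,27.8,6.0,15.0,5.0,19.2,69.8,100.4
7,45.4,10.0,2.0,20.4,5.0,14.9,64.2,95.0
8,25.0,26.3,4.8,18.4,8.4,13.7,63.8,100.8
9,25.0,25.0,10.0,17.8,5.0,19.3,62.5,90.6
10,45.4,10.0,2.0,15.0,10.4,23.2,60.2,89.0
11,32.5,17.5,10.0,15.0,7.8,17.4,59.6,93.9
12,34.0,18.7,4.3,17.8,7.8,15.3,59.8,103.0
13,25.2,27.8,2.0,15.0,12.8,19.6,55.1,83.8
14,40.0,10.0,5.0,15.0,12.8,26.3,60.5,91.2
15,25.2,27.8,2.0,22.8,5.0,20.3,58.2,89.0
16,29.5,21.8,3.2,20.3,7.9,23.8,64.4,94.7
17,25.2,27.8,2.0,15.0,12.8,20.8,55.3,84.5
18,47.8,13.0,2.0,15.0,5.0,18.2,65.1,95.3
19,45.4,10.0,2.0,20.4,5.0,16.3,63.8,99.5
20,32.5,17.5,2.0,18.0,12.8,16.0,61.9,98.7
21,41.4,10.0,10.0,16.4,5.0,16.7,58.8,87.4
22,40.4,20.4,2.0,15.0,5.0,20.1,60.7,87.4
23,33.0,27.8,2.0,15.0,5.0,19.7,56.0,86.5
24,40.0,10.0,2.0,22.8,8.0,19.0,56.7,91.2
25,40.0,10.0,5.0,15.0,12.8,22.5,58.4,90.6
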