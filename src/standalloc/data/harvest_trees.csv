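tree_no,agb,stem,branch,leaf,dbh,height
1,23.42,16.07,1.82,5.53,12.4,8.4
2,21.78,14.55,1.79,5.44,11.8,9.2
3,24.2,16.51,1.98,5.71,12.8,9.6
4,26.25,18.12,2.14,5.99,13.2,11.4
5,58.49,44.61,4.95,8.93,16.5,13
6,60.37,47.09,5.01,8.27,16.7,14.1
7,58.82,43.78,5.51,9.53,15.8,16.7
8,63.53,46.5,7.09,9.94,17.2,17.1
9,66.43,50.12,6.88,9.43,17.8,18.1
10,77.56,59.33,7.91,10.32,20.7,19.7
11,83.95,65.22,8.31,10.42,21.6,19.9
12,86.61,66.1,9.06,11.45,23.5,19.5
13,96.54,71.76,14.02,10.76,23.2,19
14,101.79,76.8,12.66,12.33,25.1,18.8
15,128.86,103.02,15.03,10.81,28.8,19.4
16,172.04,131.87,26.4,13.77,29.3,20.3
17,188.89,151.3,25.28,12.31,31.8,23.1
18,203.25,162.61,27.61,13.03,32.5,26.2
19,208.16,170.74,26.07,11.35,33.8,23.4
20,220.29,176.45,29.71,14.13,35.7,24.1
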