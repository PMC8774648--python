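ans_conc,intensity
0.0,0.0
0.5,3.765
1.0,7.597
1.5,11.27
2.0,14.94
2.5,18.575
3.0,21.94
3.5,25.648
4.0,29.01
4.5,33.077
5.0,35.918
5.5,39.088
6.0,42.314
6.5,45.373
7.0,48.355
7.5,51.53
8.0,54.714
8.5,57.396
9.0,60.564
9.5,62.953
10.0,65.693
10.5,68.81
11.0,70.999
11.5,73.074
12.0,75.57
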