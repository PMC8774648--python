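emission_nm,200,210,220,230,240,250,260,270,280,290,300,310,320,330,340,350,360,370,380,390,400
200.0,900.0,121.802,0.302,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
210.0,121.802,900.0,121.802,0.302,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
220.0,0.302,121.802,900.0,121.802,0.302,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
230.0,0.0,0.302,121.803,900.002,121.803,0.302,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
240.0,0.001,0.004,0.314,121.819,900.012,121.806,0.303,0.002,0.002,0.002,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
250.0,0.006,0.036,0.102,0.446,121.904,900.039,121.817,0.319,0.021,0.017,0.009,0.003,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
260.0,0.041,0.235,0.666,0.943,0.973,122.06,900.113,121.946,0.477,0.14,0.072,0.024,0.005,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.0
270.0,0.21,1.193,3.381,4.788,3.413,1.649,122.481,900.933,122.945,1.216,0.47,0.155,0.033,0.004,0.0,0.0,0.0,0.0,0.0,0.0,0.0
280.0,0.831,4.718,13.371,18.942,13.535,5.503,3.518,126.519,905.803,126.446,2.686,0.785,0.166,0.022,0.002,0.0,0.0,0.0,0.0,0.0,0.0
290.0,2.56,14.532,41.188,58.364,41.835,17.636,11.991,18.896,144.751,918.369,131.232,3.406,0.655,0.089,0.008,0.0,0.0,0.0,0.0,0.0,0.0
300.0,6.142,34.86,98.81,140.069,100.805,44.421,35.191,57.119,70.984,178.381,929.049,131.364,2.32,0.273,0.024,0.001,0.0,0.0,0.0,0.0,0.0
310.0,11.475,65.127,184.614,261.827,189.399,88.063,81.159,136.736,169.545,136.029,191.486,922.939,126.644,0.957,0.057,0.003,0.0,0.0,0.0,0.0,0.0
320.0,16.696,94.761,268.635,381.227,277.574,137.611,146.883,255.038,316.734,253.571,130.489,164.658,909.046,123.026,0.408,0.006,0.0,0.0,0.0,0.0,0.0
330.0,18.92,107.38,304.437,432.381,317.444,169.727,208.34,370.606,460.825,368.943,189.421,62.658,134.963,901.781,121.956,0.311,0.0,0.0,0.0,0.0,0.0
340.0,16.697,94.764,268.704,382.022,283.443,165.413,231.338,419.534,522.165,418.066,214.642,70.659,15.216,123.82,900.175,121.811,0.302,0.0,0.0,0.0,0.0
350.0,11.475,65.132,184.711,262.953,197.718,127.48,200.896,369.951,460.796,368.942,189.421,62.356,13.162,2.083,121.956,900.009,121.802,0.302,0.0,0.0,0.0
360.0,6.142,34.864,98.892,141.02,107.832,77.715,136.329,254.11,316.693,253.57,130.187,42.857,9.046,1.224,0.408,121.808,900.0,121.802,0.302,0.0,0.0
370.0,2.561,14.534,41.237,58.931,46.022,37.471,72.244,135.951,169.511,135.726,69.684,22.939,4.842,0.655,0.057,0.305,121.802,900.0,121.802,0.302,0.0
380.0,0.831,4.719,13.393,19.192,15.388,14.28,29.88,56.652,70.662,56.579,29.049,9.563,2.018,0.273,0.024,0.001,0.302,121.802,900.0,121.802,0.302
390.0,0.21,1.193,3.388,4.872,4.036,4.297,9.641,18.387,22.94,18.369,9.431,3.105,0.655,0.089,0.008,0.0,0.0,0.302,121.802,900.0,121.802
400.0,0.041,0.235,0.668,0.964,0.831,1.02,2.426,4.648,5.8,4.644,2.384,0.785,0.166,0.022,0.002,0.0,0.0,0.0,0.302,121.802,900.0
410.0,0.006,0.036,0.102,0.149,0.135,0.191,0.476,0.915,1.142,0.915,0.47,0.155,0.033,0.004,0.0,0.0,0.0,0.0,0.0,0.302,121.802
420.0,0.001,0.004,0.012,0.018,0.017,0.028,0.073,0.14,0.175,0.14,0.072,0.024,0.005,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.302
430.0,0.0,0.0,0.001,0.002,0.002,0.003,0.009,0.017,0.021,0.017,0.009,0.003,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
440.0,0.0,0.0,0.0,0.0,0.0,0.0,0.001,0.002,0.002,0.002,0.001,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
450.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
460.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
470.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
480.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
490.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
500.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
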