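wavelength_nm,point0,point1,point2,point3,point4,point5,point6,point7,point8,point9,point10
300.0,3.866,3.239,2.698,2.234,1.836,1.496,1.208,0.964,0.758,0.586,0.443
301.0,5.086,4.273,3.57,2.963,2.442,1.996,1.616,1.293,1.02,0.791,0.599
302.0,6.645,5.598,4.69,3.904,3.226,2.644,2.146,1.722,1.363,1.059,0.805
303.0,8.622,7.284,6.119,5.108,4.233,3.479,2.832,2.278,1.808,1.409,1.074
304.0,11.109,9.411,7.928,6.636,5.515,4.545,3.71,2.993,2.382,1.862,1.423
305.0,14.215,12.076,10.201,8.562,7.136,5.897,4.827,3.906,3.116,2.443,1.872
306.0,18.063,15.388,13.035,10.972,9.169,7.599,6.237,5.06,4.048,3.183,2.445
307.0,22.794,19.472,16.541,13.961,11.699,9.723,8.003,6.511,5.224,4.118,3.173
308.0,28.566,24.471,20.844,17.642,14.825,12.355,10.197,8.32,6.693,5.291,4.088
309.0,35.55,30.539,26.085,22.14,18.656,15.591,12.904,10.557,8.517,6.752,5.231
310.0,43.937,37.848,32.419,27.592,23.315,19.539,16.216,13.304,10.763,8.555,6.647
311.0,53.926,46.582,40.011,34.149,28.936,24.316,20.237,16.65,13.507,10.766,8.388
312.0,65.729,56.935,49.039,41.971,35.663,30.053,25.081,20.692,16.833,13.455,10.512
313.0,79.56,69.108,59.689,51.228,43.65,36.886,30.869,25.538,20.833,16.699,13.083
314.0,95.634,83.302,72.149,62.093,53.055,44.958,37.73,31.301,25.605,20.581,16.169
315.0,114.162,99.716,86.606,74.743,64.041,54.419,45.796,38.098,31.252,25.19,19.845
316.0,135.335,118.54,103.241,89.347,76.767,65.414,55.203,46.051,37.881,30.618,24.188
317.0,159.326,139.941,122.219,106.065,91.385,78.087,66.08,55.279,45.598,36.957,29.278
318.0,186.27,164.063,143.685,125.041,108.034,92.569,78.554,65.897,54.508,44.301,35.193
319.0,216.265,191.011,167.751,146.391,126.832,108.979,92.736,78.01,64.707,52.737,42.012
320.0,249.352,220.847,194.494,170.2,147.87,127.409,108.721,91.711,76.283,62.345,49.803
321.0,285.512,253.576,223.939,196.512,171.205,147.925,126.579,107.072,89.308,73.193,58.632
322.0,324.652,289.141,256.057,225.321,196.85,170.557,146.351,124.141,103.834,85.334,68.548
323.0,366.604,327.412,290.756,256.567,224.771,195.29,168.04,142.935,119.886,98.8,79.586
324.0,411.112,368.183,327.872,290.123,254.876,222.062,191.608,163.436,137.462,113.6,91.762
325.0,457.833,411.166,367.167,325.798,287.013,250.757,216.97,185.583,156.523,129.713,105.068
326.0,506.336,455.99,408.326,363.328,320.965,281.201,243.988,209.273,176.995,147.086,119.472
327.0,556.101,502.2,450.957,402.377,356.45,313.158,272.472,234.355,198.759,165.632,134.91
328.0,606.531,549.265,494.592,442.539,393.118,346.334,302.176,260.626,221.655,185.225,151.289
329.0,656.956,596.584,538.695,483.341,430.558,380.373,332.798,287.836,245.478,205.703,168.483
330.0,706.648,643.495,582.671,524.252,468.301,414.867,363.988,315.688,269.979,226.864,186.332
331.0,754.84,689.291,625.875,564.691,505.827,449.358,395.345,343.838,294.871,248.47,204.645
332.0,800.737,733.238,667.63,604.039,542.579,483.347,426.432,371.906,319.83,270.251,223.203
333.0,843.548,774.588,707.242,641.658,577.973,516.31,456.781,399.482,344.5,291.906,241.76
334.0,882.497,812.607,744.019,676.903,611.416,547.704,485.903,426.134,368.506,313.115,260.047
335.0,916.855,846.593,777.293,709.142,642.318,576.987,513.305,451.417,391.456,333.541,277.781
336.0,945.959,875.896,806.434,737.775,670.111,603.628,538.5,474.891,412.958,352.841,294.671
337.0,969.233,899.943,830.879,762.253,694.27,627.129,561.021,496.129,432.626,370.674,310.426
338.0,986.207,918.25,850.139,782.092,714.321,647.036,580.44,514.73,450.094,386.713,324.759
339.0,996.534,930.446,863.827,796.895,729.866,662.956,596.375,530.332,465.027,400.655,337.403
340.0,1000.0,936.28,871.661,806.358,740.588,674.566,608.507,542.626,477.13,412.226,348.113
341.0,996.534,935.63,873.479,810.287,746.267,681.629,616.589,551.362,486.161,421.197,356.678
342.0,986.207,928.51,869.243,808.601,746.785,684.0,620.455,556.362,491.934,427.384,362.924
343.0,969.233,915.067,859.041,801.334,742.132,681.629,620.024,557.523,494.331,430.661,366.724
344.0,945.959,895.578,843.084,788.637,732.404,674.566,615.306,554.819,493.303,430.961,368.0
345.0,916.855,870.439,821.698,770.769,717.802,662.956,606.398,548.308,488.869,428.275,366.724
346.0,882.497,840.15,795.311,748.093,698.623,647.036,593.483,538.123,481.123,422.662,362.924
347.0,843.548,805.304,764.445,721.06,675.25,627.129,576.824,524.472,470.223,414.235,356.678
348.0,800.737,766.561,729.692,690.194,648.143,603.628,556.752,507.63,456.389,403.167,348.113
349.0,754.84,724.632,691.699,656.077,617.818,576.987,533.66,487.929,439.896,389.678,337.403
350.0,706.648,680.256,651.146,619.331,584.837,547.704,507.986,465.747,421.066,374.035,324.759
351.0,656.956,634.179,608.729,580.596,549.785,516.31,480.2,441.496,400.252,356.535,310.426
352.0,606.531,587.131,565.136,540.518,513.257,483.347,450.793,415.612,377.834,337.502,294.671
353.0,556.101,539.811,521.035,499.724,475.841,449.358,420.259,388.538,354.204,317.274,277.781
354.0,506.336,492.871,477.051,458.811,438.099,414.867,389.081,360.714,329.753,296.195,260.047
355.0,457.833,446.898,433.757,418.333,400.559,380.373,357.723,332.565,304.866,274.602,241.76
356.0,411.112,402.409,391.662,378.786,363.701,346.334,326.617,304.491,279.907,252.821,223.203
357.0,366.604,359.842,351.206,340.605,327.95,313.158,296.151,276.858,255.212,231.158,204.645
358.0,324.652,319.55,312.749,304.152,293.666,281.201,266.669,249.99,231.086,209.888,186.332
359.0,285.512,281.806,276.575,269.721,261.147,250.757,238.46,224.167,207.792,189.256,168.483
360.0,249.352,246.801,242.893,237.533,230.621,222.062,211.76,199.621,185.554,169.471,151.289
361.0,216.265,214.648,211.837,207.738,202.255,195.29,186.748,176.532,164.549,150.705,134.91
362.0,186.27,185.392,183.473,180.423,176.149,170.557,163.55,155.034,144.911,133.089,119.472
363.0,159.326,159.015,157.807,155.616,152.352,147.925,142.243,135.211,126.735,116.719,105.068
364.0,135.335,135.447,134.792,133.29,130.858,127.409,122.856,117.107,110.071,101.654,91.762
365.0,114.162,114.574,114.337,113.377,111.618,108.979,105.376,100.725,94.936,87.921,79.586
366.0,95.634,96.247,96.315,95.772,94.548,92.569,89.758,86.035,81.316,75.516,68.548
367.0,79.56,80.292,80.572,80.341,79.535,78.087,75.926,72.979,69.168,64.413,58.632
368.0,65.729,66.518,66.936,66.929,66.442,65.414,63.781,61.476,58.428,54.563,49.803
369.0,53.926,54.726,55.223,55.371,55.121,54.419,53.208,51.427,49.013,45.899,42.012
370.0,43.937,44.712,45.244,45.492,45.412,44.958,44.08,42.724,40.832,38.343,35.193
371.0,35.55,36.278,36.812,37.116,37.154,36.886,36.266,35.247,33.78,31.81,29.278
372.0,28.566,29.232,29.744,30.073,30.188,30.053,29.63,28.878,27.753,26.207,24.188
373.0,22.794,23.391,23.867,24.198,24.358,24.316,24.041,23.496,22.643,21.441,19.845
374.0,18.063,18.587,19.018,19.336,19.518,19.539,19.371,18.985,18.347,17.421,16.169
375.0,14.215,14.668,15.05,15.344,15.531,15.591,15.5,15.234,14.763,14.057,13.083
376.0,11.109,11.495,11.827,12.092,12.274,12.355,12.317,12.139,11.796,11.264,10.512
377.0,8.622,8.946,9.23,9.463,9.632,9.723,9.72,9.606,9.361,8.963,8.388
378.0,6.645,6.914,7.154,7.354,7.507,7.599,7.618,7.549,7.377,7.083,6.647
379.0,5.086,5.307,5.506,5.676,5.81,5.897,5.928,5.891,5.773,5.558,5.231
380.0,3.866,4.045,4.208,4.351,4.465,4.545,4.582,4.566,4.487,4.332,4.088
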