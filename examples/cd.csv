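wavelength_nm,ellipticity_mdeg
200.0,1.9929
200.5,1.6709
201.0,1.2807
201.5,0.8818
202.0,0.5518
202.5,0.1555
203.0,-0.1301
203.5,-0.3954
204.0,-0.8661
204.5,-1.2124
205.0,-1.465
205.5,-1.7918
206.0,-2.1156
206.5,-2.4814
207.0,-2.7039
207.5,-2.9272
208.0,-3.3277
208.5,-3.5185
209.0,-3.8582
209.5,-4.0489
210.0,-4.3104
210.5,-4.4173
211.0,-4.6967
211.5,-4.7945
212.0,-4.9986
212.5,-5.2123
213.0,-5.5552
213.5,-5.5984
214.0,-5.736
214.5,-5.8883
215.0,-6.1549
215.5,-6.228
216.0,-6.3957
216.5,-6.5048
217.0,-6.4835
217.5,-6.7006
218.0,-6.7196
218.5,-6.7093
219.0,-6.8401
219.5,-6.8163
220.0,-6.7858
220.5,-6.7492
221.0,-6.7723
221.5,-6.5941
222.0,-6.3925
222.5,-6.4522
223.0,-6.1274
223.5,-5.9954
224.0,-5.8453
224.5,-5.4461
225.0,-5.2961
225.5,-5.1827
226.0,-4.8393
226.5,-4.5412
227.0,-4.325
227.5,-3.9956
228.0,-3.7774
228.5,-3.4613
229.0,-3.1481
229.5,-3.0385
230.0,-2.7342
230.5,-2.5453
231.0,-2.2823
231.5,-2.1613
232.0,-1.9222
232.5,-1.7116
233.0,-1.4659
233.5,-1.2911
234.0,-1.314
234.5,-1.1454
235.0,-0.9266
235.5,-0.997
236.0,-0.7943
236.5,-0.6808
237.0,-0.5091
237.5,-0.4769
238.0,-0.4829
238.5,-0.4296
239.0,-0.3718
239.5,-0.207
240.0,-0.301
240.5,-0.2582
241.0,-0.1834
241.5,-0.1891
242.0,-0.1709
242.5,-0.2129
243.0,-0.1199
243.5,-0.1336
244.0,-0.0103
244.5,-0.0332
245.0,-0.0688
245.5,-0.0125
246.0,-0.0731
246.5,0.0286
247.0,-0.0374
247.5,0.008
248.0,-0.1151
248.5,0.0004
249.0,-0.1348
249.5,-0.1554
250.0,-0.0351
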