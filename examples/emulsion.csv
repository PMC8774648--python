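A0,A10,c_g_per_mL,phi,L_cm,D
0.5,0.4,0.001,0.1,1.0,100.0
0.49501,0.39398,0.001,0.1,1.0,100.0
0.50608,0.40724,0.001,0.1,1.0,100.0
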