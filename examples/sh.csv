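A412,protein_g_per_L,path_cm,dilution
0.1436,0.368,1.0,1.0
0.141,0.368,1.0,1.0
0.1455,0.368,1.0,1.0
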