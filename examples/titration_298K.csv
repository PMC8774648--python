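ligand_conc_uM,intensity,abs_ex,abs_em
0.0,1001.524,0.0,0.0
2.0,900.084,0.01,0.002
4.0,817.04,0.02,0.004
6.0,731.645,0.03,0.006
8.0,641.578,0.04,0.008
10.0,569.671,0.05,0.01
12.0,505.417,0.06,0.012
14.0,442.545,0.07,0.014
16.0,387.974,0.08,0.016
18.0,337.89,0.09,0.018
20.0,298.296,0.1,0.02
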