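H0,H1,H2
50.0,62.6,56.3
50.0,62.4,56.448
50.0,62.8,56.208
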