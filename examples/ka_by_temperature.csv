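T_K,Ka
298,278000.0
304,267000.0
310,255000.0
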