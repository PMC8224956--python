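scaffold	length
scaffold_A	50000
scaffold_small	3000
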