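name	n_individuals	extreme	percentile_bound	trait_floor
HHDL	195	high	95	
LHDL	193	low	25	20
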