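group,xor_mean,xor_sd,xo_mean,xo_sd
non-stressed,0.802,0.099,0.556,0.091
stressed,0.694,0.079,0.523,0.081
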