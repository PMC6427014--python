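trait_set,eigenvalues
eight_traits,"5.483,1.606,0.400,0.314,0.136,0.058,0.003,0.000"
six_traits,"3.852,1.420,0.397,0.160,0.119,0.053"
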