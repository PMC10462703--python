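# Representative primary yields (species per 100 eV) for low-LET gamma /
# fast-electron irradiation of neutral water (textbook-compilation style).
species, g_value
e_aq, 2.63
H, 0.55
OH, 2.72
H2, 0.45
H2O2, 0.68
H3O+, 2.63
HO2, 0.008
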