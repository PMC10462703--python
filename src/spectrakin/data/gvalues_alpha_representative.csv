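# Representative primary yields (species per 100 eV) for high-LET alpha
# irradiation of water: molecular products enhanced, radicals suppressed.
# Illustrative values in the style of the classic textbook compilations;
# replace via the template to match a specific published row.
species, g_value
e_aq, 0.42
H, 0.27
OH, 0.54
H2, 1.15
H2O2, 1.00
H3O+, 0.42
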