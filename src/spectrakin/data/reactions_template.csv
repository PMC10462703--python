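# Blank transcription template: one row per reaction.
# reactants/products: semicolon-separated species names (empty reactants =
# zeroth-order source; untracked products such as H2O are simply omitted).
# rate_units by order: 0 -> "M s-1" | "nm-3 ns-1" | "nm-1 ns-1";
#                      1 -> "s-1" | "ns-1";
#                      2 -> "M-1 s-1" | "nm3 ns-1" | "nm ns-1".
# aa_convention (A+A rows only): "per_event" (rate = k*rho^2, default) or
# "halve" if the source table quotes the observed-loss constant 2k.
reactants, products, rate_constant, rate_units, aa_convention
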