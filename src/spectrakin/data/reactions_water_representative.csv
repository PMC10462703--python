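# Representative room-temperature rate constants for the core aqueous
# radiolysis network (standard compilation-style values). Water itself is
# not tracked; H2O appearing as a product is simply omitted. A+A rows use
# the per-event convention (rate = k*rho^2, two molecules lost per event).
# Replace via the blank template to reproduce a specific published table.
reactants, products, rate_constant, rate_units, aa_convention
e_aq;e_aq, H2;OH-;OH-, 5.5e9, M-1 s-1, per_event
e_aq;OH, OH-, 3.0e10, M-1 s-1,
e_aq;H3O+, H, 2.3e10, M-1 s-1,
e_aq;H, H2;OH-, 2.5e10, M-1 s-1,
e_aq;H2O2, OH;OH-, 1.1e10, M-1 s-1,
OH;OH, H2O2, 5.5e9, M-1 s-1, per_event
OH;H, , 7.0e9, M-1 s-1,
H;H, H2, 7.8e9, M-1 s-1, per_event
H3O+;OH-, , 1.43e11, M-1 s-1,
OH;H2, H, 4.2e7, M-1 s-1,
OH;H2O2, HO2, 2.7e7, M-1 s-1,
H;H2O2, OH, 9.0e7, M-1 s-1,
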