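# Representative diffusion coefficients for the primary water-radiolysis
# species, assembled from standard room-temperature aqueous compilations.
# These are illustrative defaults for the shipped example scenarios, not a
# transcription of any specific source table; replace with your preferred
# compilation via the blank template for quantitative work.
name, diffusion_coefficient, units
e_aq, 4.9, 1e-9 m2 s-1
OH, 2.8, 1e-9 m2 s-1
H, 7.0, 1e-9 m2 s-1
H3O+, 9.3, 1e-9 m2 s-1
OH-, 5.3, 1e-9 m2 s-1
H2, 4.8, 1e-9 m2 s-1
H2O2, 2.3, 1e-9 m2 s-1
HO2, 2.0, 1e-9 m2 s-1
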