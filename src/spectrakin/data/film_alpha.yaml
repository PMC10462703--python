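# Thin-film scenario: alpha irradiation of 2 monolayers (0.5 nm) of water
# over a perfectly absorbing oxide surface, with the representative network.
geometry: film
monolayers: 2
dose_rate: 1.0e-2        # Gy ns^-1
N: 100
dt0: 1.0e-3              # ns
tol: 1.0e-6
cross_section_nm2: 1.0
species_table: species_water_representative.csv
reaction_table: reactions_water_representative.csv
gvalue_table: gvalues_alpha_representative.csv
track_species: H2
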