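# Variant with a prescribed central minimum in the initial solvated-electron
# distribution (ballistic prechemical transit): a Gaussian minus a narrower
# Gaussian, renormalised to N0.
geometry: spur
spur_energy_eV: 100.0
b_nm: 20.0
N: 160
dt0: 1.0e-4
t_end: 3.0
tol: 1.0e-6
species_table: species_water_representative.csv
reaction_table: reactions_water_representative.csv
track_species: [e_aq, OH]
initial_gaussians:
  e_aq:  {sigma: 2.3,  N0: 4.78, hollow_sigma: 1.0, hollow_depth: 0.6}
  OH:    {sigma: 0.85, N0: 5.50}
  H3O+:  {sigma: 0.85, N0: 4.78}
  H:     {sigma: 0.85, N0: 0.62}
  H2:    {sigma: 0.85, N0: 0.15}
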