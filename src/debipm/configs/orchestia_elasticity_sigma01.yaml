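# Trait-elasticity map: orchestia_gammarellus, sigma(Y) = 0.1, 1% perturbations
species: orchestia_gammarellus
regime:
  EY_low: 0.4
  EY_high: 1.0
  sigma_Y: 0.1
grid:
  p: {start: 0.05, stop: 0.95, num: 11}
  q: {start: 0.05, stop: 0.95, num: 11}
sim:
  total_steps: 3000
  burn_in: 500
  n_cells: 200
  seed: 1
  replicates: 1
output:
  directory: results/orchestia_elasticity_sigma01
  prefix: orchestia_sigma01
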