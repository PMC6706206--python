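# Trait-elasticity map: manta_alfredi, sigma(Y) = 0.5, 1% perturbations
species: manta_alfredi
regime:
  EY_low: 0.5
  EY_high: 0.9
  sigma_Y: 0.5
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
  directory: results/manta_elasticity_sigma05
  prefix: manta_sigma05
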