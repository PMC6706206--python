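# debipm

Stochastic **dynamic-energy-budget integral projection models** (DEB-IPMs)
for size-structured populations in randomly switching feeding environments.

## The problem

How does the *color* of environmental noise — whether good and bad feeding
conditions arrive in long runs (red noise), independently (white), or in
alternation (blue) — affect the long-run growth rate and body-size structure
of a population, and does the answer differ between fast and slow life
histories?  `debipm` answers this mechanistically: instead of perturbing
statistical demographic rates, every demographic function follows from an
individual's energy budget and the current expected feeding level
`E(Y) ∈ [0, 1]`.  The package ships two parameterisations at opposite ends
of the fast–slow continuum: the beach hopper *Orchestia gammarellus* (a
salt-marsh amphipod; monthly time step) and the reef manta ray
*Manta alfredi* (yearly time step).

It is aimed at population ecologists and stochastic demographers who want a
trait-based alternative to matrix-model perturbation studies.

## The model

One time step of the body-length distribution `N(L, t)` on the length
domain Ω follows

```
N(L', t+1) = ∫_Ω [ D(L') R(L) + G(L', L) S(L) ] N(L, t) dL
```

with four fundamental functions driven by `E(Y)`:

- **Survival** `S(L) = exp(−µ)` for `L ≤ L_m E(Y)/κ`, else 0.  Individuals
  whose maintenance exceeds assimilated energy starve; `κ` is the fraction
  of ingested energy allocated to somatic maintenance and growth.
- **Growth** `G(L', L)`: Gaussian around the von Bertalanffy mean
  `E[L'] = L e^(−r_B) + (1 − e^(−r_B)) L_m E(Y)` with standard deviation
  `(1 − e^(−r_B)) L_m σ(Y)`; `σ(Y)` is the feeding-level variability, the
  model's channel for demographic stochasticity.
- **Reproduction** `R(L) = E(Y) R_m L² / L_m²` for mature, non-starved
  lengths `L_p ≤ L ≤ L_m E(Y)/κ`, else 0.
- **Offspring size** `D(L')`: Gaussian around a fixed offspring mean
  (equal to the length at birth `L_b`), a point mass when its variance is 0.

The environment is a two-state Markov chain: a good state (feeding level
`EY_high`) and a bad state (`EY_low`) with switch probabilities `p`
(good→bad) and `q` (bad→good).  Its serial autocorrelation is
`ρ = 1 − p − q` (red `ρ>0`, white `ρ=0`, blue `ρ<0`) and the stationary
good-state frequency is `f = q/(p+q)`.  Iterating `p(t+1) = A(t) p(t)`
over the simulated state sequence gives the log stochastic growth rate
`log λ_s = (1/τ) Σ r_t` with `r_t = log(N_{t+1}/N_t)`, and the pooled mean
body size (the grand mean over time of the per-step population mean
length).  Elasticities of `log λ_s` to the six life-history traits
(`L_b, L_p, L_m, R_m, r_B, µ`) come from 1% proportional perturbations
rerun on the same environment sequence.

## Worked example

```python
import debipm as d

params = d.species_preset("orchestia_gammarellus")   # Table of traits, mm/month
regime = d.FeedingRegime(p=0.5, q=0.5,               # white noise, f = 0.5
                         EY_low=0.4, EY_high=1.0, sigma_Y=0.1)
result = d.project(params, regime, d.SimConfig(seed=1))
print(f"log lambda_s = {result.log_lambda_s:.4f} per month")
print(f"pooled mean body size = {result.pooled_mean_size:.3f} mm")
```

prints

```
log lambda_s = 0.0566 per month
pooled mean body size = 5.216 mm
```

a growing population (about 5.8% per month) whose size distribution,
averaged over 2,500 retained steps, centres on 5.2 mm — newborn-heavy, as
expected when reproduction is high.  The same analysis from the shell:

```bash
$ debipm lambda manta 0.75          # deterministic eigen-analysis
dominant lambda:    1.068888 per year
stable mean size:   299.0645 cm

$ debipm estimate-mortality         # dummy-survivorship regression
mu = 0.2712 month^-1 (rounded: 0.27)

$ debipm sweep src/debipm/configs/orchestia_growth_rate_sigma01.yaml
$ debipm elasticity src/debipm/configs/manta_elasticity_sigma01.yaml
```

Grid sweeps and elasticity maps write long-format CSV tables
(`p, q, rho, f, log_lambda_s, pooled_mean_size`, or per-trait elasticities
plus the dominant trait per cell) along with a JSON run manifest; pass
`--plot` for contour renderings.

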