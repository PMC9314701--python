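# hssd — hierarchical species sensitivity distributions for nano- and microplastics

`hssd` fits Bayesian hierarchical log-normal species sensitivity
distributions (SSDs) to chronic toxicity data for nano- and microplastic
(NMP) particles, and derives hazardous concentrations for 5% of species
(HC5) under explicit exposure scenarios. It is aimed at ecotoxicologists and
risk assessors who want SSDs that account for the properties of the tested
particles — diameter, polymer type, freshwater vs. marine medium — instead of
pooling heterogeneous effect concentrations into a single distribution.

## The model

Each observation is a chronic lowest-observed-effect concentration (LOEC,
μg/L) for one species under one test condition, from study (reference) *j*:

```
log10 LOEC_i ~ Normal(μ_i, σ)
μ_i = α + β_size·log10(d_i) + β_media·M_i + β_polymer·P_i + r_j(i)
r_j ~ Normal(0, σ_Ref)
```

where `d` is particle diameter (μm), `M` the medium dummy (freshwater 0,
marine 1), `P` the polymer dummy (non-polystyrene 0, PS 1), and `r_j` a
per-study random intercept absorbing unmodeled between-study factors with
spread `σ_Ref`. Priors are noninformative (flat on locations, flat on the
scales over the positive half-line, realised as wide proper uniforms). All
8 subsets of the three predictors are candidate models; they are fitted by
an exact conjugate Gibbs sampler (3 chains, 20,000 burn-in, 10,000 draws
thinned to every 10th → 3,000 retained; split-chain R̂ < 1.1 required) and
ranked by WAIC. The HC5 for a scenario is the 5th percentile of the fitted
SSD, `10^(μ + Φ⁻¹(0.05)·σ)`, per posterior draw — by default excluding the
study effects, optionally re-inflating the uncertainty with a fresh
`Normal(0, σ_Ref)` perturbation per draw.

## Worked example

```python
from hssd import (SamplerConfig, SyntheticConfig, generate,
                  preprocess_records, fit_and_rank)

records, truth = generate(SyntheticConfig(seed=11))   # synthetic NMP dataset
data = preprocess_records(records)                    # 28 obs, 15 references
table, fits = fit_and_rank(data, SamplerConfig(seed=1))
best = fits[table.best_label]
print(best.summary().round(3))
```

```
              median  ci_2.5  ci_97.5   rhat
parameter
alpha          3.227   2.475    4.008  1.000
beta_size     -0.350  -0.714    0.023  1.000
beta_polymer  -1.653  -2.473   -0.816  1.000
sigma          0.846   0.614    1.202  1.000
sigma_ref      0.386   0.022    0.925  1.004
```

The WAIC ranking selected `size+polymer` for this dataset: the SSD mean
falls by ~0.35 log10 units per decade of particle diameter and is ~1.7 log10
units lower for polystyrene particles; `sigma` is the interspecies spread of
the SSD and `sigma_ref` the between-study spread, both in log10 μg/L.

```python
h = best.hc5(size_um=0.1, medium="marine", polymer_is_ps=True, seed=2)
# HC5 (0.1 um, marine, PS): 3.43 ug/L (95% CrI 0.43-16.7)
hre = best.hc5(size_um=0.1, medium="marine", polymer_is_ps=True,
               include_random_effects=True, seed=2)
# with random effects:      3.22 ug/L (95% CrI 0.172-54.9)
```

The HC5 median is the concentration below which 95% of species are expected
to be unaffected; adding the study-level random effect leaves the median
nearly unchanged but widens the credible interval substantially — the
between-study heterogeneity dominates the uncertainty of "safe"
concentrations.

## Command line

The same pipeline is scriptable:

```bash
hssd simulate records.csv --seed 11
hssd preprocess records.csv prepared.csv
hssd fit-select prepared.csv fit/ --seed 1          # rank_table.csv + posterior stores
hssd hc5 fit/posterior_size_media scenarios.csv hc5.csv --seed 2
```

Every stage appends a JSON-lines manifest (seeds, config hashes, R̂
summaries) so stochastic results are auditable. Real datasets enter as a
record CSV (one effect concentration per row with species, effect type,
exposure duration, particle size or size range, shape, polymer, medium,
reference id); preprocessing converts reported values to chronic LOECs with
a user-editable extrapolation-factor table (factors 1–30), keeps spherical
particles, resolves brackish media, and aggregates replicates to geometric
means.

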