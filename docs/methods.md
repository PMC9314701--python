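# Methods

## Model

Interspecies variation in sensitivity to nano- and microplastic (NMP)
particles is described by a log-normal species sensitivity distribution
(SSD) whose mean depends on particle and test properties. For observation
*i* (one chronic LOEC, μg/L) from study *j*:

    log10 LOEC_i ~ Normal(mu_i, sigma)
    mu_i = alpha + beta_size * log10(d_i) + beta_media * M_i
                 + beta_polymer * P_i + r_j
    r_j ~ Normal(0, sigma_ref)

with particle diameter `d` in μm, medium dummy `M` (freshwater 0, marine 1)
and polymer dummy `P` (non-PS 0, PS 1 — polystyrene and PS–polyethyleneimine
mixtures are coded PS because other polymers are too sparse to distinguish).
`sigma` (log10 μg/L) is the interspecies spread of the SSD, assumed constant
across particle properties; `sigma_ref` is the spread of study-level random
intercepts capturing unmodeled between-study factors (particle origin,
stabiliser removal, test practice). The candidate set is all 8 subsets of
the three fixed-effect predictors; the random intercept is present in every
candidate.

Assumptions worth stating plainly: effect concentrations are exchangeable
within a study given the covariates; the response is a *chronic LOEC*, so
derived HC5 values are less conservative than NOEC-based ones; and sampling
a species twice under different conditions contributes two observations (the
SSD describes species-by-condition sensitivities, not one value per
species).

## Preprocessing

Reported effect concentrations (LC50/EC50/NOEC/LOEC) are divided by an
extrapolation factor in [1, 30] resolved from a user-editable (effect type,
exposure-duration window) table; records already carrying chronic LOECs pass
through with factor 1, and the applied factor is retained for audit. The
shipped default table is illustrative only — compiled datasets normally come
with their own conversion or pre-converted values. Only spherical particles
are kept (fibers/fragments confound shape with the modelled properties);
brackish tests are reassigned to marine unless a per-species override maps
them to freshwater. When a size range is reported, the arithmetic mean of
its bounds is used. Replicate effect concentrations under identical
conditions (species × size × polymer class × medium × reference) collapse to
their geometric mean; the grouping key deliberately includes the reference
so each aggregated record belongs to exactly one study — same-condition
records from different references are reported but never merged across
studies, since the random effect requires a single study per observation.

## Priors and sampling

Priors are noninformative: flat over each location parameter and flat over
`sigma > 0`, `sigma_ref > 0`. For propriety under any sampler they are
realised as wide proper uniforms, ±50 on locations and (0, 50] on scales
(log10 μg/L units, far outside any plausible posterior; configurable via
`PriorBounds`).

Under these priors every full conditional is closed-form, so the sampler is
an exact Gibbs scheme: multivariate-normal updates for (alpha, beta) on the
random-effect-adjusted response, normal updates for each `r_j` with
precision `n_j/sigma^2 + 1/sigma_ref^2`, and truncated inverse-gamma updates
for `sigma^2` (shape (n−1)/2) and `sigma_ref^2` (shape (J−1)/2). Because the
conditionals are exact there is no step-size tuning and no funnel-geometry
pathology to re-parameterise away, so no non-centered variant is provided.
Prior bounds are enforced by rejection with an inverse-CDF fallback for the
scales. Sampling `sigma_ref` requires at least two references; otherwise it
must be pinned (`fix_sigma_ref`), which also provides the exact
non-hierarchical limit used in the least-squares cross-checks.

The default run is 3 chains × (20,000 burn-in + 10,000 draws thinned to
every 10th) = 1,000 retained per chain, 3,000 total — a deliberately long
profile that makes the Monte-Carlo error on medians negligible at ~30
observations while still fitting all eight candidates in under a minute. A
fast profile (3 × 2,000/2,000, thin 1) serves tests and exploration.
Convergence is monitored with the split-chain Gelman–Rubin statistic (each
chain halved before comparing between- and within-chain variance — the more
conservative modern form); any parameter at R̂ ≥ 1.1 raises a
`ConvergenceWarning`, never a silent pass. Identical seed + config + data
reproduce draws bit for bit; chains derive independent streams from a
`SeedSequence` spawn.

## Model selection

WAIC is computed from the pointwise log posterior densities,
`waic = −2(lppd − p_waic)` on the deviance scale, with `lppd_i` via
log-sum-exp and `p_waic_i` the across-draw variance (ddof = 1, the
convention of the standard information-criterion tooling; consequently exact
invariance under draw duplication holds only up to the (S−1)→(2S−1)
denominator change). The pointwise density is conditional on the sampled
`r_j`, matching standard generated-quantities practice; a `marginal=True`
variant integrates the random effect out analytically
(`sd = sqrt(sigma^2 + sigma_ref^2)`) for sensitivity analysis. Candidates
are ranked by ascending WAIC; ties break toward fewer predictors, then
label order. No ΔWAIC cutoff is imposed — there is no accepted threshold, so
the table reports raw differences.

## HC5 derivation

For a scenario (diameter, medium, optional polymer class) each retained draw
gives `mu_s` from the fixed effects only; `HCp_s = 10^(mu_s + z_p·sigma_s)`
with `z_p = Phi^{-1}(p)` computed at run time (never the 4-digit constant,
so the round-trip identity "fraction affected at HCp equals p" holds to
machine precision). The protected fraction defaults to p = 0.05 (HC5) and is
a parameter, since HC1/HC10 are also used in regulation. Excluding `r_j`
targets the HC5 free of study-specific artefacts; with
`include_random_effects` one fresh `Normal(0, sigma_ref_s)` perturbation per
posterior draw (a single perturbation, not one per reference) propagates
between-study heterogeneity into the interval. Scenario sizes outside the
fitted size range are flagged as extrapolations. Summaries use linear-
interpolation percentiles (2.5/50/97.5), pooled across chains, everywhere.

## Synthetic data

The generator draws exactly from the model above: per reference an
intercept `r_j`, per observation a diameter log-uniform on 0.04–315 μm (the
span of compiled NMP chronic data, heavy-tailed in size), medium ~
Bernoulli(16/26 marine), polymer ~ Bernoulli(22/26 PS), then the Gaussian
response. Default true parameters sit at the central estimates published for
this data regime (alpha 3.20, beta_size −0.21, beta_media −0.95,
beta_polymer −1.09, sigma 0.72, sigma_ref 0.92) with 15 references of 1–3
observations (~30 records), so recovery experiments run at realistic
difficulty. What the generator does *not* emulate: real compiled datasets
have correlated covariates (PS dominates small sizes), repeated species,
reporting error in sizes and durations, and non-random study selection —
passing recovery tests therefore demonstrates correctness of the estimator
under the model, not robustness to those features.

The recovery harness replicates generate → fit → score, reporting per-
parameter posterior-median absolute error and empirical 95%-credible-
interval coverage. At 20 replicates, J = 15 and n ≈ 30–200, coverage is
checked against the binomial band [0.7, 1.0] and the average error must
shrink with n; note that with J fixed, the errors of `alpha` and `sigma_ref`
are floored by the number of studies, so the improvement with n comes mostly
from the slopes and `sigma`.

## Numerical choices and degenerate inputs

- Rank-deficient designs (a constant dummy column, possible at small n with
  extreme class probabilities) raise an explicit error rather than sampling
  an unidentified posterior.
- `sigma_ref = 0` is admissible only with all `r_j = 0` (the degenerate
  random effect); the prior returns −∞ otherwise.
- Empty datasets, non-finite responses, nonpositive concentrations/sizes and
  inverted size ranges are rejected with named errors at the boundary.
- The sum of squares entering the scale updates is floored at 1e−30 to keep
  the gamma draw defined when residuals vanish.
- Percentile convention: linear interpolation between order statistics
  (numpy default), stated once and used for every summary and HC5 interval.

## Problem sizes

Tests run the fast sampler profile on ~30-observation synthetic datasets
(the scale of compiled NMP chronic data); the acceptance script uses the
full long profile for the eight-model fit and the fast profile for the
replicated recovery experiment (10 replicates), sizes chosen so the entire
analysis reruns from scratch in well under a minute on one core.

## Known limitations

- The exact published extrapolation-factor mapping is not redistributed;
  users supply their own table (or pre-converted chronic LOECs).
- The SSD spread `sigma` is not modelled as a function of particle
  properties (data too sparse to identify it).
- No particle-to-body-size ratio predictor, no mode-of-action or
  bioavailability correction, and no study-quality weighting.
- WAIC conditional on `r_j` favours models partly through the random effect;
  the marginal variant is provided but not the default.
- LOEC-based HC5 values are less conservative than NOEC-based ones and
  should be interpreted as likely ranges, not regulatory thresholds.
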