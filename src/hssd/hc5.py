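"""SSD curves and hazardous-concentration (HC5) posteriors per exposure scenario.

For a scenario (particle size, medium, optionally polymer class) each
posterior draw s yields an SSD mean

    mu_s = alpha_s + beta_size,s * log10(size) + beta_media,s * medium_dummy
           [+ beta_polymer,s * polymer_dummy]

with terms present per the fitted model, and the hazardous concentration for
a fraction p of species (default p = 0.05, the HC5) is the p-th quantile of
the log-normal SSD:

    HCp_s = 10 ** (mu_s + z_p * sigma_s),   z_p = Phi^{-1}(p).

By default mu excludes the reference intercepts, so the HC5 is unaffected by
study-specific unmodeled factors; with ``include_random_effects`` a single
fresh perturbation r*_s ~ Normal(0, sigma_ref_s) is added to mu_s per draw,
propagating the between-study spread into the HC5 uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConfigurationError
from .sampler import PosteriorSamples


@dataclass(frozen=True)
class Scenario:
    """One exposure condition for which an SSD / HC5 is derived."""

    size_um: float
    medium: str  # "freshwater" or "marine"
    polymer_is_ps: bool | None = None
    include_random_effects: bool = False

    def __post_init__(self) -> None:
        if not self.size_um > 0:
            raise ValueError(f"size_um must be > 0, got {self.size_um}")
        if self.medium not in ("freshwater", "marine"):
            raise ValueError(f"medium must be freshwater or marine, got {self.medium!r}")


@dataclass
class Hc5Result:
    """Posterior draws and summaries of HCp (ug/L) for one scenario."""

    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    scenario: Scenario
    hcp: float = 0.05
    extrapolation_note: bool = False

    def __post_init__(self) -> None:
        assert self.ci_low <= self.median <= self.ci_high
        assert np.all(self.draws > 0)


def ssd_fraction_affected(conc_ug_l, mu, sigma):
    """Fraction of species affected at a concentration: the SSD's CDF.

    Standard normal CDF of (log10(conc) - mu) / sigma; strictly increasing in
    concentration. ``conc_ug_l`` must be positive.
    """
    conc = np.asarray(conc_ug_l, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentration must be > 0")
    return stats.norm.cdf((np.log10(conc) - mu) / sigma)


def _mu_fixed(samples: PosteriorSamples, scenario: Scenario) -> np.ndarray:
    spec = samples.spec
    mu = samples.flat("alpha").copy()
    if spec.use_size:
        mu += samples.flat("beta_size") * np.log10(scenario.size_um)
    if spec.use_media:
        mu += samples.flat("beta_media") * (1.0 if scenario.medium == "marine" else 0.0)
    if spec.use_polymer:
        if scenario.polymer_is_ps is None:
            raise ConfigurationError(
                f"model {spec.label!r} includes polymer; scenario must set polymer_is_ps"
            )
        mu += samples.flat("beta_polymer") * (1.0 if scenario.polymer_is_ps else 0.0)
    elif scenario.polymer_is_ps:
        raise ConfigurationError(
            f"scenario sets polymer_is_ps but model {spec.label!r} has no polymer term"
        )
    return mu


def _mu_draws(
    samples: PosteriorSamples, scenario: Scenario, seed: int | None
) -> np.ndarray:
    mu = _mu_fixed(samples, scenario)
    if scenario.include_random_effects:
        # one fresh study-level perturbation per posterior draw
        rng = np.random.default_rng(seed)
        mu = mu + rng.standard_normal(mu.size) * samples.flat("sigma_ref")
    return mu


def hc5_draws(
    samples: PosteriorSamples,
    scenario: Scenario,
    seed: int | None = None,
    hcp: float = 0.05,
    fitted_size_range: tuple[float, float] | None = None,
) -> Hc5Result:
    """Posterior distribution of the hazardous concentration for ``hcp`` of species.

    ``fitted_size_range`` (um) flags the result as an extrapolation when the
    scenario size lies outside the sizes the model was fitted to. z_p is
    computed from the inverse normal CDF at run time.
    """
    if not 0 < hcp < 1:
        raise ValueError("hcp must lie in (0, 1)")
    mu = _mu_draws(samples, scenario, seed)
    z = stats.norm.ppf(hcp)
    draws = 10.0 ** (mu + z * samples.flat("sigma"))
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    note = False
    if fitted_size_range is not None:
        note = not (fitted_size_range[0] <= scenario.size_um <= fitted_size_range[1])
    return Hc5Result(
        draws=draws, median=float(med), ci_low=float(lo), ci_high=float(hi),
        scenario=scenario, hcp=hcp, extrapolation_note=note,
    )


def ssd_curve(
    samples: PosteriorSamples,
    scenario: Scenario,
    conc_grid: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pointwise median and 95% band of the fraction affected over a grid.

    Returns a frame with columns conc_ug_l, median, ci_2.5, ci_97.5; the
    median curve is nondecreasing in concentration. The grid must be positive
    and sorted ascending.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if np.any(grid <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(np.diff(grid) < 0):
        raise ValueError("concentration grid must be sorted ascending")
    mu = _mu_draws(samples, scenario, seed)
    sigma = samples.flat("sigma")
    frac = stats.norm.cdf(
        (np.log10(grid)[None, :] - mu[:, None]) / sigma[:, None]
    )
    lo, med, hi = np.percentile(frac, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {"conc_ug_l": grid, "median": med, "ci_2.5": lo, "ci_97.5": hi}
    )


def hc5_table(
    samples: PosteriorSamples,
    scenarios: list[Scenario],
    seed: int | None = None,
    hcp: float = 0.05,
    fitted_size_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Scenario-grid HC5 table (medium, size, median, CI, extrapolation flag)."""
    seeds = (
        np.random.SeedSequence(seed).generate_state(len(scenarios)) % (2 ** 31)
        if seed is not None
        else [None] * len(scenarios)
    )
    rows = []
    for sc, s in zip(scenarios, seeds):
        res = hc5_draws(
            samples, sc, seed=None if s is None else int(s), hcp=hcp,
            fitted_size_range=fitted_size_range,
        )
        rows.append(
            {
                "medium": sc.medium,
                "size_um": sc.size_um,
                "hc5_median": res.median,
                "hc5_ci_2.5": res.ci_low,
                "hc5_ci_97.5": res.ci_high,
                "random_effects": sc.include_random_effects,
                "extrapolated": res.extrapolation_note,
            }
        )
    return pd.DataFrame(rows)
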