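"""Fitted-model results: posterior summaries, WAIC, SSD curves and HC5."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hc5 import Hc5Result, Scenario, hc5_draws, hc5_table, ssd_curve
from .sampler import PosteriorSamples, posterior_summary
from .selection import WaicResult, waic


class HssdResults:
    """Posterior of one candidate HSSD model fitted to a dataset.

    Carries the retained MCMC draws, convergence diagnostics (split-chain
    R-hat per parameter) and methods deriving the quantities of interest:
    parameter summaries, WAIC, SSD curves and HC5 posteriors per scenario.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- diagnostics ------------------------------------------------------
    @property
    def spec(self):
        return self.samples.spec

    @property
    def rhat(self) -> dict[str, float]:
        return self.samples.rhat

    @property
    def converged(self) -> bool:
        """True when every parameter's R-hat is below the config threshold."""
        thr = self.samples.config.rhat_threshold
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(vals) and max(vals) < thr

    # -- estimates --------------------------------------------------------
    def posterior_median(self, name: str) -> float:
        return float(np.median(self.samples.flat(name)))

    def summary(self, include_random_effects: bool = False) -> pd.DataFrame:
        """Posterior medians and 95% credible intervals per parameter."""
        return posterior_summary(self.samples, include_random_effects)

    def waic(self, marginal: bool = False) -> WaicResult:
        return waic(self.samples, self.model.data, marginal=marginal)

    # -- derived quantities ----------------------------------------------
    @property
    def fitted_size_range(self) -> tuple[float, float] | None:
        """Particle-size range (um) the model was fitted to, for extrapolation flags."""
        if not self.spec.use_size:
            return None
        xs = self.model.data.x_size
        return (float(10.0 ** xs.min()), float(10.0 ** xs.max()))

    def hc5(
        self,
        size_um: float = 0.1,
        medium: str = "marine",
        polymer_is_ps: bool | None = None,
        include_random_effects: bool = False,
        seed: int | None = None,
        hcp: float = 0.05,
    ) -> Hc5Result:
        scenario = Scenario(size_um, medium, polymer_is_ps, include_random_effects)
        return hc5_draws(
            self.samples, scenario, seed=seed, hcp=hcp,
            fitted_size_range=self.fitted_size_range,
        )

    def hc5_table(
        self, scenarios: list[Scenario], seed: int | None = None, hcp: float = 0.05
    ) -> pd.DataFrame:
        return hc5_table(
            self.samples, scenarios, seed=seed, hcp=hcp,
            fitted_size_range=self.fitted_size_range,
        )

    def ssd_curve(
        self,
        conc_grid: np.ndarray,
        size_um: float = 0.1,
        medium: str = "marine",
        polymer_is_ps: bool | None = None,
        include_random_effects: bool = False,
        seed: int | None = None,
    ) -> pd.DataFrame:
        scenario = Scenario(size_um, medium, polymer_is_ps, include_random_effects)
        return ssd_curve(self.samples, scenario, conc_grid, seed=seed)

    # -- persistence ------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        self.samples.save(prefix)

    def __str__(self) -> str:
        head = (
            f"HSSD model [{self.spec.label}]  n_obs={self.model.data.n_obs}  "
            f"n_refs={self.model.data.n_refs}  draws={self.samples.n_total}  "
            f"max R-hat={max(v for v in self.rhat.values() if np.isfinite(v)):.3f}"
        )
        return head + "\n" + self.summary().to_string()
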