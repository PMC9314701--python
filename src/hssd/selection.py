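"""WAIC computation and ranking of the eight candidate HSSD models.

WAIC (widely applicable information criterion) is computed from the pointwise
posterior log densities: lppd_i = log mean_s p(y_i | theta_s), penalised by
p_waic_i = Var_s log p(y_i | theta_s), and reported on the deviance scale
waic = -2 (lppd - p_waic). Smaller is better. The pointwise density is by
default *conditional* on the sampled reference intercepts r_j; the marginal
variant integrates them out analytically, y_i ~ Normal(fixed part,
sqrt(sigma^2 + sigma_ref^2)).

Candidates are ranked by ascending WAIC; delta-WAIC is relative to the
minimum. No "competitive-model" cutoff is applied — the table reports raw
delta-WAIC only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .model import ModelSpec
from .preprocess import PreparedDataset
from .sampler import PosteriorSamples


def pointwise_loglik_matrix(
    samples: PosteriorSamples, data: PreparedDataset, marginal: bool = False
) -> np.ndarray:
    """(n_draws_total, n_obs) matrix of log p(y_i | draw s).

    Conditional on the sampled r_j by default; with ``marginal=True`` the
    random effect is integrated out of the Gaussian instead.
    """
    spec = samples.spec
    mu = samples.flat("alpha")[:, None] * np.ones((1, data.n_obs))
    if spec.use_size:
        mu = mu + samples.flat("beta_size")[:, None] * data.x_size[None, :]
    if spec.use_media:
        mu = mu + samples.flat("beta_media")[:, None] * data.x_media[None, :]
    if spec.use_polymer:
        mu = mu + samples.flat("beta_polymer")[:, None] * data.x_polymer[None, :]
    sigma = samples.flat("sigma")[:, None]
    if marginal:
        sd = np.sqrt(sigma ** 2 + samples.flat("sigma_ref")[:, None] ** 2)
        return stats.norm.logpdf(data.y[None, :], mu, sd)
    r_flat = samples.r.reshape(-1, samples.n_refs)
    mu = mu + r_flat[:, np.asarray(data.ref_index, int)]
    return stats.norm.logpdf(data.y[None, :], mu, sigma)


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_contributions: np.ndarray  # per-observation -2*(lppd_i - p_waic_i)

    def __post_init__(self) -> None:
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def waic(
    samples: PosteriorSamples, data: PreparedDataset, marginal: bool = False
) -> WaicResult:
    """WAIC on the deviance scale for one fitted model.

    Requires at least 2 retained draws (the penalty is a sample variance).
    lppd_i uses a numerically stable log-sum-exp over draws.
    """
    ll = pointwise_loglik_matrix(samples, data, marginal=marginal)
    s = ll.shape[0]
    if s < 2:
        raise ValueError("WAIC needs >= 2 retained draws")
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_waic_i = ll.var(axis=0, ddof=1)
    return WaicResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_waic_i.sum()),
        waic=float(-2.0 * (lppd_i.sum() - p_waic_i.sum())),
        pointwise_contributions=-2.0 * (lppd_i - p_waic_i),
    )


@dataclass
class RankTable:
    """Candidate models ordered by WAIC (best first)."""

    frame: pd.DataFrame  # columns: rank, model, size, media, polymer, waic, delta_waic

    @property
    def best_label(self) -> str:
        return str(self.frame.iloc[0]["model"])

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        for col in ("size", "media", "polymer"):
            out[col] = np.where(out[col], "+", "")
        out.to_csv(path, index=False, encoding="utf-8")

    def __str__(self) -> str:
        return self.frame.to_string(index=False)


def rank_models(results: list[tuple[ModelSpec, WaicResult]]) -> RankTable:
    """Rank candidates by ascending WAIC; delta_waic relative to the minimum.

    Ties are broken by fewer predictors, then label order (recorded in the
    stable sort key, not hidden).
    """
    if not results:
        raise ValueError("no models to rank")
    rows = [
        {
            "model": spec.label,
            "size": spec.use_size,
            "media": spec.use_media,
            "polymer": spec.use_polymer,
            "n_predictors": spec.n_predictors,
            "waic": w.waic,
            "lppd": w.lppd,
            "p_waic": w.p_waic,
        }
        for spec, w in results
    ]
    df = pd.DataFrame(rows).sort_values(
        ["waic", "n_predictors", "model"], kind="stable", ignore_index=True
    )
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    cols = ["rank", "model", "size", "media", "polymer", "waic", "delta_waic",
            "lppd", "p_waic"]
    return RankTable(df[cols])


def fit_and_rank(
    data: PreparedDataset,
    config=None,
    specs: list[ModelSpec] | None = None,
    marginal: bool = False,
):
    """Fit every candidate model and rank by WAIC.

    Returns ``(RankTable, {label: HssdResults})``. Seeds are derived per model
    from ``config.seed`` so candidates are independent but reproducible.
    """
    from dataclasses import replace

    from .model import HssdModel, enumerate_models
    from .sampler import SamplerConfig

    config = config or SamplerConfig()
    specs = specs if specs is not None else enumerate_models()
    fits: dict[str, object] = {}
    scored: list[tuple[ModelSpec, WaicResult]] = []
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(specs)) % (
        2 ** 31
    )
    for spec, seed in zip(specs, child_seeds):
        res = HssdModel(data, spec).fit(replace(config, seed=int(seed)))
        fits[spec.label] = res
        scored.append((spec, waic(res.samples, data, marginal=marginal)))
    return rank_models(scored), fits
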