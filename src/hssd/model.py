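"""Hierarchical log-normal species sensitivity distribution (HSSD) model.

The SSD describes interspecies variation in sensitivity to NMP particles as

    log10 LOEC_i ~ Normal(mu_i, sigma)
    mu_i = alpha + beta_size * x_size_i + beta_media * x_media_i
                 + beta_polymer * x_polymer_i + r_{j(i)}
    r_j ~ Normal(0, sigma_ref)

where x_size is log10 particle diameter (um), x_media the medium dummy
(freshwater 0, marine 1), x_polymer the polymer dummy (non-PS 0, PS 1) and
r_j a per-reference (per-study) random intercept with spread sigma_ref
capturing unmodeled between-study variation. Each candidate model includes a
subset of the three fixed-effect predictors — eight candidates in total — and
always the random effect.

Priors are noninformative: flat on the location parameters (alpha, betas) and
flat on sigma > 0 and sigma_ref > 0. For propriety under any sampler they are
realised as wide proper uniforms with configurable bounds
(:class:`PriorBounds`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import PreparedDataset

_PREDICTORS = ("size", "media", "polymer")


class ConfigurationError(ValueError):
    """A model spec requests a predictor the data or scenario cannot supply."""


@dataclass(frozen=True)
class ModelSpec:
    """Which of the three fixed-effect predictors a candidate model includes."""

    use_size: bool = False
    use_media: bool = False
    use_polymer: bool = False

    @property
    def label(self) -> str:
        parts = [p for p, u in zip(_PREDICTORS, self.included()) if u]
        return "+".join(parts) if parts else "null"

    def included(self) -> tuple[bool, bool, bool]:
        return (self.use_size, self.use_media, self.use_polymer)

    @property
    def n_predictors(self) -> int:
        return sum(self.included())

    @property
    def fixed_effect_names(self) -> tuple[str, ...]:
        names = ["alpha"]
        names += [f"beta_{p}" for p, u in zip(_PREDICTORS, self.included()) if u]
        return tuple(names)

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        label = label.strip().lower()
        if label in ("null", ""):
            return cls()
        parts = set(label.split("+"))
        unknown = parts - set(_PREDICTORS)
        if unknown:
            raise ConfigurationError(
                f"unknown predictors {sorted(unknown)}; expected subset of {_PREDICTORS}"
            )
        return cls("size" in parts, "media" in parts, "polymer" in parts)


def enumerate_models() -> list[ModelSpec]:
    """All 8 predictor subsets in deterministic order (null first, full last)."""
    specs = [
        ModelSpec(*flags)
        for flags in itertools.product((False, True), repeat=3)
    ]
    specs.sort(key=lambda s: (s.n_predictors, s.label))
    return specs


@dataclass(frozen=True)
class PriorBounds:
    """Wide proper uniform bounds standing in for flat priors.

    loc_bound bounds alpha and each beta to [-loc_bound, loc_bound]
    (log10 ug/L scale); scale_upper bounds sigma and sigma_ref to
    (0, scale_upper].
    """

    loc_bound: float = 50.0
    scale_upper: float = 50.0


@dataclass
class HssdParams:
    """One point in parameter space (e.g. one posterior draw)."""

    alpha: float
    sigma: float
    sigma_ref: float
    r: np.ndarray
    beta_size: float | None = None
    beta_media: float | None = None
    beta_polymer: float | None = None


def mean_function(
    params: HssdParams,
    spec: ModelSpec,
    x_size: np.ndarray | None = None,
    x_media: np.ndarray | None = None,
    x_polymer: np.ndarray | None = None,
    ref_index: np.ndarray | None = None,
) -> np.ndarray:
    """SSD mean mu_i = alpha + sum(beta * x) + r_j, terms present per spec."""
    pieces = []
    for use, beta, x, name in (
        (spec.use_size, params.beta_size, x_size, "size"),
        (spec.use_media, params.beta_media, x_media, "media"),
        (spec.use_polymer, params.beta_polymer, x_polymer, "polymer"),
    ):
        if not use:
            continue
        if x is None:
            raise ConfigurationError(f"spec includes {name} but no x_{name} column given")
        if beta is None:
            raise ConfigurationError(f"spec includes {name} but beta_{name} is unset")
        pieces.append(beta * np.asarray(x, dtype=float))
    if ref_index is None:
        raise ConfigurationError("ref_index is required (pass zeros for no grouping)")
    mu = params.alpha + np.asarray(params.r, dtype=float)[np.asarray(ref_index, int)]
    for piece in pieces:
        mu = mu + piece
    return mu


def log_likelihood_pointwise(
    params: HssdParams, spec: ModelSpec, data: PreparedDataset
) -> np.ndarray:
    """Per-observation Normal log density of y at (mu, sigma), given r."""
    if not params.sigma > 0:
        raise ValueError(f"sigma must be > 0, got {params.sigma}")
    mu = mean_function(
        params, spec, data.x_size, data.x_media, data.x_polymer, data.ref_index
    )
    return stats.norm.logpdf(data.y, loc=mu, scale=params.sigma)


def log_prior(params: HssdParams, bounds: PriorBounds = PriorBounds()) -> float:
    """Log prior density up to a constant.

    Flat over each location parameter within +-loc_bound and over the two
    scales on (0, scale_upper]; -inf outside. The reference intercepts
    contribute sum_j log Normal(r_j | 0, sigma_ref) at the current sigma_ref.
    """
    locs = [params.alpha] + [
        b for b in (params.beta_size, params.beta_media, params.beta_polymer)
        if b is not None
    ]
    if any(abs(v) > bounds.loc_bound for v in locs):
        return -np.inf
    if not (0 < params.sigma <= bounds.scale_upper):
        return -np.inf
    r = np.asarray(params.r, dtype=float)
    if params.sigma_ref == 0:
        # degenerate random effect: admissible only with all r_j = 0
        return 0.0 if not np.any(r) else -np.inf
    if not (0 < params.sigma_ref <= bounds.scale_upper):
        return -np.inf
    return float(np.sum(stats.norm.logpdf(r, scale=params.sigma_ref)))


def log_posterior(
    params: HssdParams,
    spec: ModelSpec,
    data: PreparedDataset,
    bounds: PriorBounds = PriorBounds(),
) -> float:
    lp = log_prior(params, bounds)
    if not np.isfinite(lp):
        return -np.inf
    return lp + float(np.sum(log_likelihood_pointwise(params, spec, data)))


class HssdModel:
    """Hierarchical SSD model bound to a prepared dataset.

    Parameters
    ----------
    data : PreparedDataset
        Encoded response and predictors (see :mod:`hssd.preprocess`).
    spec : ModelSpec, optional
        Fixed-effect predictor subset; defaults to the full model.
    bounds : PriorBounds, optional
        Uniform prior bounds.

    Examples
    --------
    >>> model = HssdModel(data, ModelSpec.from_label("size+media"))
    >>> res = model.fit(SamplerConfig.fast(seed=1))
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: PreparedDataset,
        spec: ModelSpec | None = None,
        bounds: PriorBounds = PriorBounds(),
    ):
        if data.n_obs == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(data.y)):
            raise ValueError("non-finite response values")
        self.data = data
        self.spec = spec if spec is not None else ModelSpec(True, True, True)
        self.bounds = bounds
        if data.n_obs < self.spec.n_predictors + 3:
            raise ValueError(
                f"n_obs={data.n_obs} too small for {self.spec.label} "
                f"({self.spec.n_predictors + 1} fixed effects + 2 scales)"
            )

    @classmethod
    def from_records(cls, records, spec=None, **preprocess_kwargs) -> "HssdModel":
        from .preprocess import preprocess_records

        return cls(preprocess_records(records, **preprocess_kwargs), spec)

    @classmethod
    def from_dataframe(cls, df, spec=None) -> "HssdModel":
        """Build from a prepared-dataset frame (columns y, x_*, reference_id)."""
        return cls(PreparedDataset.from_frame(df), spec)

    @property
    def exog(self) -> np.ndarray:
        """Fixed-effect design matrix (intercept + included predictors)."""
        cols = [np.ones(self.data.n_obs)]
        for use, x in (
            (self.spec.use_size, self.data.x_size),
            (self.spec.use_media, self.data.x_media),
            (self.spec.use_polymer, self.data.x_polymer),
        ):
            if use:
                cols.append(np.asarray(x, dtype=float))
        return np.column_stack(cols)

    @property
    def endog(self) -> np.ndarray:
        return self.data.y

    def loglike_pointwise(self, params: HssdParams) -> np.ndarray:
        return log_likelihood_pointwise(params, self.spec, self.data)

    def logposterior(self, params: HssdParams) -> float:
        return log_posterior(params, self.spec, self.data, self.bounds)

    def fit(self, config=None, fix_sigma_ref: float | None = None):
        """Draw posterior samples; returns an :class:`~hssd.results.HssdResults`.

        fix_sigma_ref pins the random-effect spread at a constant instead of
        sampling it (useful for the non-hierarchical limit sigma_ref ~ 0).
        """
        from .results import HssdResults
        from .sampler import SamplerConfig, sample_posterior

        config = config or SamplerConfig()
        samples = sample_posterior(
            self.data, self.spec, config, bounds=self.bounds,
            fix_sigma_ref=fix_sigma_ref,
        )
        return HssdResults(self, samples)
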