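"""Posterior sampling for the hierarchical SSD model.

Under the flat priors every full conditional of the model is closed-form, so
the sampler is an exact Gibbs scheme:

* (alpha, beta) | r, sigma   — multivariate normal (weighted least squares on
  the random-effect-adjusted response);
* r_j | beta, sigma, sigma_ref — normal, precision n_j/sigma^2 + 1/sigma_ref^2;
* sigma^2 | ...              — inverse gamma (flat prior on sigma);
* sigma_ref^2 | r            — inverse gamma (flat prior on sigma_ref).

The wide uniform prior bounds are enforced by rejection (they are essentially
never active for real datasets). The default configuration mirrors a
long-run setup — 3 chains, 20,000 burn-in, 10,000 draws thinned to every
10th, i.e. 1,000 retained per chain and 3,000 in total — with a fast profile
for tests. Identical seed + config + data give bit-identical draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConfigurationError, ModelSpec, PriorBounds
from .preprocess import PreparedDataset


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when any R-hat exceeds its threshold."""


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    Defaults: 3 chains, 20,000 burn-in iterations discarded, 10,000 sampling
    iterations thinned to every 10th — 1,000 retained draws per chain, 3,000
    total. Convergence is flagged against ``rhat_threshold`` (default 1.1).
    """

    n_chains: int = 3
    n_burnin: int = 20_000
    n_draws: int = 10_000
    thin: int = 10
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_burnin", "n_draws", "thin"):
            if getattr(self, name) < (0 if name == "n_burnin" else 1):
                raise ValueError(f"{name} must be positive")
        if self.n_draws % self.thin:
            raise ValueError(
                f"thin={self.thin} must divide n_draws={self.n_draws} evenly"
            )

    @property
    def n_kept_per_chain(self) -> int:
        return self.n_draws // self.thin

    @property
    def n_kept_total(self) -> int:
        return self.n_kept_per_chain * self.n_chains

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "SamplerConfig":
        """Reduced profile for tests and exploration (3 x 2,000/2,000, thin 1)."""
        return cls(n_chains=3, n_burnin=2_000, n_draws=2_000, thin=1, seed=seed, **kw)


def gelman_rubin(per_chain_draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic R-hat for one parameter.

    Each chain is halved, doubling the chain count, before comparing the
    between-chain variance of the split means with the mean within-chain
    variance; the split form also detects within-chain trends. Input shape is
    (n_chains, n_draws); requires >= 2 chains and >= 4 draws per chain.
    """
    draws = np.asarray(per_chain_draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("expected a 2-D (chains, draws) array")
    m, n = draws.shape
    if m < 2:
        raise ValueError("R-hat needs >= 2 chains; run a multi-chain sampler")
    if n < 4:
        raise ValueError("R-hat needs >= 4 draws per chain")
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    b = half * split.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


@dataclass
class PosteriorSamples:
    """Retained posterior draws, indexed (chain, retained draw).

    ``params`` maps each scalar parameter name (alpha, beta_*, sigma,
    sigma_ref) to a (n_chains, n_kept) array; ``r`` holds the reference
    intercepts with shape (n_chains, n_kept, n_refs). ``rhat`` carries the
    split-chain diagnostic per parameter.
    """

    params: dict[str, np.ndarray]
    r: np.ndarray
    spec: ModelSpec
    config: SamplerConfig
    rhat: dict[str, float]
    ref_ids: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return int(next(iter(self.params.values())).size)

    @property
    def n_refs(self) -> int:
        return self.r.shape[-1]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        if name.startswith("r["):
            j = int(name[2:-1])
            return self.r[:, :, j].reshape(-1)
        return self.params[name].reshape(-1)

    @property
    def names(self) -> list[str]:
        return list(self.params) + [f"r[{j}]" for j in range(self.n_refs)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format draws: columns chain, draw, parameter, value."""
        n_chains, n_kept = next(iter(self.params.values())).shape
        chain = np.repeat(np.arange(n_chains), n_kept)
        draw = np.tile(np.arange(n_kept), n_chains)
        frames = []
        for name in self.names:
            if name.startswith("r["):
                vals = self.flat(name)
            else:
                vals = self.params[name].reshape(-1)
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "draw": draw, "parameter": name, "value": vals}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save(self, prefix: str | Path) -> None:
        """Persist draws to <prefix>.csv (long format) + <prefix>.json sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        sidecar = {
            "spec": self.spec.label,
            "config": {
                "n_chains": self.config.n_chains,
                "n_burnin": self.config.n_burnin,
                "n_draws": self.config.n_draws,
                "thin": self.config.thin,
                "seed": self.config.seed,
                "rhat_threshold": self.config.rhat_threshold,
            },
            "rhat": self.rhat,
            "ref_ids": list(self.ref_ids),
        }
        prefix.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "PosteriorSamples":
        prefix = Path(prefix)
        side = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
        df = pd.read_csv(prefix.with_suffix(".csv"))
        config = SamplerConfig(**side["config"])
        n_chains = int(df["chain"].max()) + 1
        n_kept = int(df["draw"].max()) + 1
        params: dict[str, np.ndarray] = {}
        r_cols: dict[int, np.ndarray] = {}
        for name, grp in df.groupby("parameter", sort=False):
            arr = (
                grp.sort_values(["chain", "draw"])["value"]
                .to_numpy()
                .reshape(n_chains, n_kept)
            )
            if name.startswith("r["):
                r_cols[int(name[2:-1])] = arr
            else:
                params[name] = arr
        r = np.stack([r_cols[j] for j in sorted(r_cols)], axis=-1) if r_cols else (
            np.zeros((n_chains, n_kept, 0))
        )
        return cls(
            params=params,
            r=r,
            spec=ModelSpec.from_label(side["spec"]),
            config=config,
            rhat={k: float(v) for k, v in side["rhat"].items()},
            ref_ids=tuple(side.get("ref_ids", ())),
        )


def _design(data: PreparedDataset, spec: ModelSpec) -> np.ndarray:
    cols = [np.ones(data.n_obs)]
    if spec.use_size:
        cols.append(np.asarray(data.x_size, float))
    if spec.use_media:
        cols.append(np.asarray(data.x_media, float))
    if spec.use_polymer:
        cols.append(np.asarray(data.x_polymer, float))
    return np.column_stack(cols)


def _trunc_inv_gamma_scale2(
    rng: np.random.Generator, shape: float, ss: float, upper: float
) -> float:
    """Draw sigma^2 with density prop. to (s2)^-(shape+1) exp(-ss/(2 s2)),
    truncated to sqrt(s2) <= upper. Sampled through the gamma-distributed
    precision; truncation by rejection with an inverse-CDF fallback."""
    ss = max(ss, 1e-30)
    tau_min = upper ** -2
    for _ in range(100):
        tau = rng.gamma(shape, 2.0 / ss)
        if tau >= tau_min:
            return 1.0 / tau
    # nearly all mass below the bound: inverse-CDF on the truncated region
    lo = stats.gamma.cdf(tau_min, shape, scale=2.0 / ss)
    u = lo + rng.uniform() * (1.0 - lo)
    tau = stats.gamma.ppf(min(u, 1.0 - 1e-16), shape, scale=2.0 / ss)
    return 1.0 / max(tau, tau_min)


def sample_posterior(
    data: PreparedDataset,
    spec: ModelSpec,
    config: SamplerConfig | None = None,
    bounds: PriorBounds = PriorBounds(),
    fix_sigma_ref: float | None = None,
) -> PosteriorSamples:
    """Gibbs-sample the HSSD posterior for one candidate model.

    Parameters
    ----------
    fix_sigma_ref : float, optional
        Pin sigma_ref at this value instead of sampling it (0 gives the
        non-hierarchical limit with all r_j = 0). When sampled, at least two
        references are required for the spread to be identifiable.

    Returns retained draws after burn-in and thinning, with split-chain R-hat
    per parameter; warns (ConvergenceWarning) if any R-hat >= the threshold.
    """
    config = config or SamplerConfig()
    if data.n_obs == 0:
        raise ValueError("empty dataset")
    if not np.all(np.isfinite(data.y)):
        raise ValueError("non-finite response values")
    p = spec.n_predictors + 1
    if data.n_obs < p + 2:
        raise ValueError(f"n_obs={data.n_obs} < {p + 2} required for {spec.label}")
    if fix_sigma_ref is None and data.n_refs < 2:
        raise ValueError(
            "sampling sigma_ref needs >= 2 references; pass fix_sigma_ref instead"
        )
    if fix_sigma_ref is not None and fix_sigma_ref < 0:
        raise ValueError("fix_sigma_ref must be >= 0")

    x = _design(data, spec)
    y = data.y
    n, j_refs = data.n_obs, data.n_refs
    ref = np.asarray(data.ref_index, int)
    n_per_ref = np.bincount(ref, minlength=j_refs).astype(float)

    xtx = x.T @ x
    if np.linalg.matrix_rank(x) < p:
        raise ValueError(
            f"design matrix for {spec.label!r} is rank-deficient "
            "(a predictor column is constant or collinear)"
        )
    xtx_inv = np.linalg.inv(xtx)
    chol_xtx_inv = np.linalg.cholesky(xtx_inv)
    proj = xtx_inv @ x.T  # (p, n): beta_hat = proj @ y_adj

    # OLS start for all chains, dispersed by per-chain jitter
    beta_hat0, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid0 = y - x @ beta_hat0
    sigma0 = max(float(resid0.std(ddof=min(p, n - 1))), 1e-3)

    n_kept = config.n_kept_per_chain
    keep_names = list(spec.fixed_effect_names) + ["sigma", "sigma_ref"]
    out = {name: np.empty((config.n_chains, n_kept)) for name in keep_names}
    out_r = np.empty((config.n_chains, n_kept, j_refs))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        beta = beta_hat0 + sigma0 * (chol_xtx_inv @ rng.standard_normal(p))
        sigma2 = sigma0 ** 2 * np.exp(rng.uniform(-0.5, 0.5))
        if fix_sigma_ref is not None:
            sr2 = float(fix_sigma_ref) ** 2
        else:
            sr2 = max(sigma0 ** 2 * np.exp(rng.uniform(-0.5, 0.5)), 1e-6)
        r = (np.sqrt(sr2) * rng.standard_normal(j_refs)) if sr2 > 0 else np.zeros(j_refs)

        kept = 0
        total = config.n_burnin + config.n_draws
        for it in range(total):
            # -- reference intercepts r_j
            e = y - x @ beta
            if sr2 > 0:
                prec = n_per_ref / sigma2 + 1.0 / sr2
                mean_r = (np.bincount(ref, weights=e, minlength=j_refs) / sigma2) / prec
                r = mean_r + rng.standard_normal(j_refs) / np.sqrt(prec)
            else:
                r = np.zeros(j_refs)

            # -- fixed effects (alpha, betas)
            y_adj = y - r[ref]
            mean_beta = proj @ y_adj
            for _ in range(100):
                beta = mean_beta + np.sqrt(sigma2) * (
                    chol_xtx_inv @ rng.standard_normal(p)
                )
                if np.all(np.abs(beta) <= bounds.loc_bound):
                    break
            else:
                beta = np.clip(mean_beta, -bounds.loc_bound, bounds.loc_bound)

            # -- residual scale sigma
            resid = y_adj - x @ beta
            sigma2 = _trunc_inv_gamma_scale2(
                rng, (n - 1) / 2.0, float(resid @ resid), bounds.scale_upper
            )

            # -- random-effect scale sigma_ref
            if fix_sigma_ref is None:
                sr2 = _trunc_inv_gamma_scale2(
                    rng, (j_refs - 1) / 2.0, float(r @ r), bounds.scale_upper
                )

            k = it - config.n_burnin
            if k >= 0 and (k + 1) % config.thin == 0:
                for name, val in zip(spec.fixed_effect_names, beta):
                    out[name][c, kept] = val
                out["sigma"][c, kept] = np.sqrt(sigma2)
                out["sigma_ref"][c, kept] = np.sqrt(sr2)
                out_r[c, kept] = r
                kept += 1
        assert kept == n_kept

    rhat: dict[str, float] = {}
    can_rhat = config.n_chains >= 2 and n_kept >= 4
    for name in keep_names:
        rhat[name] = gelman_rubin(out[name]) if can_rhat else np.nan
    for jj in range(j_refs):
        rhat[f"r[{jj}]"] = gelman_rubin(out_r[:, :, jj]) if can_rhat else np.nan

    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v >= config.rhat_threshold}
    if bad:
        warnings.warn(
            f"R-hat >= {config.rhat_threshold} for {sorted(bad)}; "
            "increase burn-in/draws",
            ConvergenceWarning,
            stacklevel=2,
        )

    return PosteriorSamples(
        params=out, r=out_r, spec=spec, config=config, rhat=rhat,
        ref_ids=data.ref_ids,
    )


def posterior_summary(
    samples: PosteriorSamples, include_random_effects: bool = False
) -> pd.DataFrame:
    """Median and central 95% credible interval per parameter.

    Percentiles (2.5th, 50th, 97.5th) use linear interpolation between order
    statistics, pooling retained draws across chains.
    """
    names = list(samples.params)
    if include_random_effects:
        names += [f"r[{j}]" for j in range(samples.n_refs)]
    rows = []
    for name in names:
        draws = samples.flat(name)
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        rows.append(
            {"parameter": name, "median": med, "ci_2.5": lo, "ci_97.5": hi,
             "rhat": samples.rhat.get(name, np.nan)}
        )
    return pd.DataFrame(rows).set_index("parameter")
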