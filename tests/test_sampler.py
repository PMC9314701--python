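"""Gibbs sampler contracts, convergence diagnostics and posterior summaries."""

import numpy as np
import pytest

from hssd import (
    HssdModel,
    ModelSpec,
    PosteriorSamples,
    SamplerConfig,
    SyntheticConfig,
    gelman_rubin,
    generate,
    posterior_summary,
    preprocess_records,
    sample_posterior,
)

from conftest import make_samples


class TestSamplerConfig:
    def test_default_retains_3000_draws(self):
        cfg = SamplerConfig()
        assert cfg.n_chains == 3
        assert cfg.n_kept_per_chain == 1000
        assert cfg.n_kept_total == 3000

    def test_thin_must_divide_draws(self):
        with pytest.raises(ValueError, match="thin"):
            SamplerConfig(n_draws=1000, thin=3)


class TestGelmanRubin:
    def test_matches_hand_computed_split_formula(self):
        # 2 chains x 4 draws; oracle below evaluates B/W on the 4 half-chains
        draws = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 4.0, 6.0]])
        split = np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 2.0], [4.0, 6.0]])
        n = 2
        w = split.var(axis=1, ddof=1).mean()
        b = n * split.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(draws) == pytest.approx(expected, rel=1e-12)

    def test_same_distribution_chains_approach_one(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(4, 20_000))
        assert gelman_rubin(draws) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2, 500)) + np.array([[0.0], [10.0]])
        assert gelman_rubin(draws) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            gelman_rubin(np.zeros((1, 100)))

    def test_constant_draws_return_one(self):
        assert gelman_rubin(np.ones((3, 10))) == 1.0

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(3, 400)).cumsum(axis=1) * 0.01 + rng.normal(
            size=(3, 400)
        )
        ours = gelman_rubin(draws)
        theirs = float(az.rhat(draws, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSamplePosterior:
    def test_same_seed_bit_identical(self, paper_scale_data):
        data, _ = paper_scale_data
        cfg = SamplerConfig(n_burnin=50, n_draws=100, thin=2, seed=5)
        a = sample_posterior(data, ModelSpec(True, True, False), cfg)
        b = sample_posterior(data, ModelSpec(True, True, False), cfg)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])
        np.testing.assert_array_equal(a.r, b.r)

    def test_different_seed_differs(self, paper_scale_data):
        data, _ = paper_scale_data
        cfg = SamplerConfig(n_burnin=50, n_draws=100, thin=2, seed=5)
        a = sample_posterior(data, ModelSpec(), cfg)
        b = sample_posterior(data, ModelSpec(), SamplerConfig(
            n_burnin=50, n_draws=100, thin=2, seed=6))
        assert not np.array_equal(a.params["alpha"], b.params["alpha"])

    def test_scale_draws_respect_support(self, fitted_size_media):
        s = fitted_size_media.samples
        assert np.all(s.flat("sigma") > 0)
        assert np.all(s.flat("sigma_ref") > 0)
        assert np.all(s.flat("sigma") <= 50.0)

    def test_rhat_reported_for_all_parameters(self, fitted_size_media):
        s = fitted_size_media.samples
        expected = {"alpha", "beta_size", "beta_media", "sigma", "sigma_ref"} | {
            f"r[{j}]" for j in range(s.n_refs)
        }
        assert set(s.rhat) == expected
        assert all(np.isfinite(v) for v in s.rhat.values())

    def test_retained_count_contract(self, fitted_size_media):
        s = fitted_size_media.samples
        assert s.params["alpha"].shape == (3, s.config.n_kept_per_chain)
        assert s.n_total == s.config.n_kept_total

    def test_empty_dataset_rejected(self):
        from hssd.preprocess import PreparedDataset

        empty = PreparedDataset(
            y=np.array([]), x_size=np.array([]), x_media=np.array([]),
            x_polymer=np.array([]), ref_index=np.array([], dtype=int), ref_ids=(),
        )
        with pytest.raises(ValueError, match="empty"):
            sample_posterior(empty, ModelSpec())

    def test_single_reference_requires_fixed_sigma_ref(self):
        records, _ = generate(SyntheticConfig(seed=1, n_refs=1, obs_per_ref=10))
        data = preprocess_records(records)
        with pytest.raises(ValueError, match="references"):
            sample_posterior(data, ModelSpec(), SamplerConfig.fast())
        out = sample_posterior(
            data, ModelSpec(),
            SamplerConfig(n_burnin=50, n_draws=100, thin=1, seed=0),
            fix_sigma_ref=0.0,
        )
        assert np.all(out.flat("sigma_ref") == 0.0)
        assert np.all(out.r == 0.0)

    def test_row_permutation_leaves_posterior_distribution_unchanged(
        self, paper_scale_data
    ):
        data, _ = paper_scale_data
        rng = np.random.default_rng(9)
        perm = rng.permutation(data.n_obs)
        from hssd.preprocess import PreparedDataset

        # re-index references by first appearance in the permuted order
        ref_ids_perm = []
        seen = {}
        new_index = []
        for i in perm:
            rid = data.ref_ids[data.ref_index[i]]
            if rid not in seen:
                seen[rid] = len(ref_ids_perm)
                ref_ids_perm.append(rid)
            new_index.append(seen[rid])
        permuted = PreparedDataset(
            y=data.y[perm], x_size=data.x_size[perm], x_media=data.x_media[perm],
            x_polymer=data.x_polymer[perm], ref_index=np.array(new_index),
            ref_ids=tuple(ref_ids_perm),
        )
        cfg = SamplerConfig.fast(seed=3)
        spec = ModelSpec(True, True, False)
        a = sample_posterior(data, spec, cfg)
        b = sample_posterior(permuted, spec, cfg)
        for name in ("alpha", "beta_size", "sigma", "sigma_ref"):
            assert np.median(a.flat(name)) == pytest.approx(
                np.median(b.flat(name)), abs=0.1
            )


class TestPosteriorSummary:
    def test_median_by_linear_interpolation(self):
        spec = ModelSpec()
        draws = np.arange(1.0, 101.0).reshape(1, 100)
        s = make_samples(
            spec,
            {"alpha": draws, "sigma": np.ones((1, 100)), "sigma_ref": np.ones((1, 100))},
            np.zeros((1, 100, 1)),
        )
        summ = posterior_summary(s)
        assert summ.loc["alpha", "median"] == pytest.approx(50.5)

    def test_constant_draws_degenerate_interval(self):
        spec = ModelSpec()
        c = 3.7 * np.ones((1, 10))
        s = make_samples(spec, {"alpha": c, "sigma": c, "sigma_ref": c},
                         np.zeros((1, 10, 1)))
        row = posterior_summary(s).loc["alpha"]
        assert row["median"] == row["ci_2.5"] == row["ci_97.5"] == 3.7

    def test_covers_model_parameters(self, fitted_size_media):
        summ = fitted_size_media.summary()
        assert list(summ.index) == ["alpha", "beta_size", "beta_media", "sigma",
                                    "sigma_ref"]
        assert (summ["ci_2.5"] <= summ["median"]).all()
        assert (summ["median"] <= summ["ci_97.5"]).all()

    def test_random_effects_included_on_request(self, fitted_size_media):
        summ = fitted_size_media.summary(include_random_effects=True)
        assert any(str(ix).startswith("r[") for ix in summ.index)


def test_ols_limit_with_sigma_ref_fixed_near_zero():
    """With the random effect pinned at ~0 and flat priors the posterior mean
    of (alpha, beta) matches ordinary least squares."""
    import statsmodels.api as sm

    records, _ = generate(
        SyntheticConfig(seed=21, n_refs=10, obs_per_ref=20, true_sigma_ref=0.0)
    )
    data = preprocess_records(records)
    res = HssdModel(data, ModelSpec(True, True, False)).fit(
        SamplerConfig.fast(seed=4), fix_sigma_ref=0.0
    )
    x = sm.add_constant(np.column_stack([data.x_size, data.x_media]))
    ols = sm.OLS(data.y, x).fit()
    for i, name in enumerate(("alpha", "beta_size", "beta_media")):
        post_mean = res.samples.flat(name).mean()
        assert post_mean == pytest.approx(ols.params[i], abs=4 * ols.bse[i] / 10)


def test_posterior_store_round_trip(tmp_path, fitted_size_media):
    prefix = tmp_path / "store" / "posterior_size_media"
    fitted_size_media.save(prefix)
    back = PosteriorSamples.load(prefix)
    assert back.spec == fitted_size_media.spec
    for name in fitted_size_media.samples.params:
        np.testing.assert_allclose(
            back.params[name], fitted_size_media.samples.params[name]
        )
    np.testing.assert_allclose(back.r, fitted_size_media.samples.r)
    assert back.rhat.keys() == fitted_size_media.samples.rhat.keys()
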