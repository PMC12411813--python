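"""Gibbs sampler correctness, diagnostics and posterior behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isofoodweb.hier_model import (
    ModelConfig,
    PosteriorDraws,
    _Design,
    fit,
    location_posterior_moments,
    rhat,
    significance,
)


def _small_data(rng, n=60, groups=("a", "b"), sites=("s1", "s2", "s3")):
    g = rng.choice(groups, n)
    s = rng.choice(sites, n)
    inv = rng.random(n) < 0.5
    length = rng.normal(100, 20, n)
    y = (
        np.where(g == "a", 5.0, 2.0)
        + 0.02 * (length - 100)
        - 0.8 * inv
        + rng.normal(0, 0.5, n)
    )
    return pd.DataFrame(
        {"group": g, "site_id": s, "invaded": inv, "length_mm": length,
         "d15n_adjusted": y, "d13c_permil": -24 + y * 0.1}
    )


def _draws_from_arrays(alpha, n_chains):
    """Minimal PosteriorDraws wrapper around a (n_chains*keep,) alpha vector."""
    n = alpha.shape[0]
    keep = n // n_chains
    filler = np.linspace(0.1, 1.0, n)[:, None]
    return PosteriorDraws(
        response="d15n_adjusted", groups=["g"], sites=["s"],
        alpha=alpha[:, None], beta1=filler.copy(), beta2=filler.copy(),
        gamma=filler.copy(), sigma=filler[:, 0] + 1, tau=filler[:, 0],
        chain=np.repeat(np.arange(n_chains), keep),
        draw=np.tile(np.arange(keep), n_chains),
        length_center={"g": 0.0}, length_range={"g": (0.0, 1.0)},
        obs_counts={("g", True): 1, ("g", False): 1},
        n_chains=n_chains, n_iter=keep, n_burnin=0,
    )


class TestConfig:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            ModelConfig(n_iter=100, n_burnin=100)

    def test_single_chain_warns(self):
        with pytest.warns(UserWarning, match="R-hat"):
            ModelConfig(n_chains=1)


class TestSampler:
    def test_retained_draw_count_at_defaults(self, d15n_draws):
        """3 chains x (1500 - 750) burnt-in iterations = 2250 kept samples."""
        assert d15n_draws.n_draws == 2250
        assert np.all(d15n_draws.sigma > 0)
        assert np.all(d15n_draws.tau >= 0)

    def test_conjugate_oracle_moments(self):
        """With tau=0 and sigma known the location posterior is closed-form
        Gaussian; the sampler's conditional must match an independently
        assembled ridge-regression oracle."""
        rng = np.random.default_rng(3)
        data = _small_data(rng)
        config = ModelConfig(fix_tau=0.0, fix_sigma=0.5, seed=1)
        design = _Design(data, config)
        mean, cov = location_posterior_moments(design, sigma=0.5, tau=0.0)

        # oracle: build X explicitly, posterior precision = X'X/s2 + P
        groups = sorted(data["group"].unique())
        X = []
        for kind in range(3):
            for g in groups:
                m = (data["group"] == g).to_numpy().astype(float)
                if kind == 0:
                    X.append(m)
                elif kind == 1:
                    lg = data["length_mm"].to_numpy() - data.loc[data["group"] == g, "length_mm"].mean()
                    X.append(m * lg)
                else:
                    X.append(m * data["invaded"].to_numpy().astype(float))
        X = np.column_stack(X)
        y = data["d15n_adjusted"].to_numpy()
        P = np.diag(design.theta_prior_prec)
        prec = X.T @ X / 0.25 + P
        want_cov = np.linalg.inv(prec)
        want_mean = want_cov @ (X.T @ y / 0.25 + P @ design.theta_prior_mean)

        p = design.p
        np.testing.assert_allclose(mean[:p], want_mean, rtol=1e-9)
        np.testing.assert_allclose(cov[:p, :p], want_cov, rtol=1e-8)

    def test_conjugate_oracle_empirical_draws(self):
        rng = np.random.default_rng(4)
        data = _small_data(rng)
        config = ModelConfig(fix_tau=0.0, fix_sigma=0.5, seed=2,
                             n_iter=4000, n_burnin=0)
        draws = fit(data, config)
        design = _Design(data, config)
        mean, cov = location_posterior_moments(design, sigma=0.5, tau=0.0)
        emp = np.concatenate([draws.alpha.mean(0), draws.beta1.mean(0), draws.beta2.mean(0)])
        se = np.sqrt(np.diag(cov)[: design.p] / draws.n_draws)
        assert np.all(np.abs(emp - mean[: design.p]) < 5 * se)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        data = _small_data(rng)
        cfg = ModelConfig(seed=9, n_iter=200, n_burnin=100)
        a = fit(data, cfg)
        b = fit(data, cfg)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_exchangeability_of_record_order(self):
        rng = np.random.default_rng(6)
        data = _small_data(rng, n=120)
        cfg = ModelConfig(seed=3, n_iter=1500, n_burnin=500)
        a = fit(data, cfg)
        b = fit(data.sample(frac=1.0, random_state=0).reset_index(drop=True), cfg)
        for name in a.parameter_names():
            va, vb = a.get(name), b.get(name)
            mc = va.std(ddof=1) / np.sqrt(len(va))
            assert abs(va.mean() - vb.mean()) < 8 * mc + 1e-6, name

    def test_fewer_than_two_sites_rejected(self):
        rng = np.random.default_rng(7)
        data = _small_data(rng, sites=("only",))
        with pytest.raises(ValueError, match="tau"):
            fit(data, ModelConfig())

    def test_single_level_group_warns(self):
        rng = np.random.default_rng(8)
        data = _small_data(rng)
        data.loc[data["group"] == "a", "invaded"] = True
        with pytest.warns(UserWarning, match="one invasion level"):
            _Design(data, ModelConfig())

    def test_prior_predictive_matches_prior(self):
        """Zero-weight likelihood: intercept draws follow their Gaussian prior."""
        rng = np.random.default_rng(9)
        data = _small_data(rng)
        cfg = ModelConfig(seed=4, prior_only=True, n_iter=2000, n_burnin=500)
        draws = fit(data, cfg)
        y = data["d15n_adjusted"]
        stat = stats.kstest(
            draws.alpha[:, 0], "norm", args=(y.mean(), 2.5 * y.std(ddof=1))
        )
        assert stat.pvalue > 0.01

    def test_site_effects_shrink_toward_zero(self, adjusted, d15n_draws):
        """Partial pooling: posterior-mean site effects vary less than raw
        per-site residual means."""
        post_gamma = d15n_draws.gamma.mean(axis=0)
        resid = adjusted.copy()
        # remove group/status/length structure with the posterior means
        groups = d15n_draws.groups
        a = dict(zip(groups, d15n_draws.alpha.mean(0)))
        b1 = dict(zip(groups, d15n_draws.beta1.mean(0)))
        b2 = dict(zip(groups, d15n_draws.beta2.mean(0)))
        pred = resid.apply(
            lambda r: a[r["group"]]
            + b1[r["group"]] * (r["length_mm"] - d15n_draws.length_center[r["group"]])
            + b2[r["group"]] * r["invaded"],
            axis=1,
        )
        raw_site_means = (resid["d15n_adjusted"] - pred).groupby(resid["site_id"]).mean()
        assert post_gamma.std(ddof=1) <= raw_site_means.std(ddof=1) + 1e-9

    def test_channel_invasion_effect_recovered_negative(self, d15n_draws):
        assert d15n_draws.get("beta2[channel_catfish]").mean() < 0


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(11)
        rep = rhat(_draws_from_arrays(rng.standard_normal(2000), 2))
        assert 1.0 <= rep.rhat["alpha[g]"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(12)
        alpha = np.concatenate([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        rep = rhat(_draws_from_arrays(alpha, 2))
        assert rep.rhat["alpha[g]"] > 1.1
        assert not rep.converged

    def test_constant_chains_reported_missing(self):
        rep = rhat(_draws_from_arrays(np.full(2000, 2.5), 2))
        assert np.isnan(rep.rhat["alpha[g]"])
        assert any("alpha[g]" in w for w in rep.warnings)

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            rhat(_draws_from_arrays(rng.standard_normal(1000), 1))

    def test_default_fit_converged(self, d15n_draws):
        assert rhat(d15n_draws).converged


class TestSignificance:
    def test_constant_positive_excludes_zero(self):
        d = _draws_from_arrays(np.ones(2000), 2)
        res = significance(d, "alpha[g]")
        assert res.lo == res.hi == 1.0 and res.excludes_zero

    def test_symmetric_includes_zero(self):
        rng = np.random.default_rng(14)
        d = _draws_from_arrays(rng.standard_normal(2000), 2)
        assert not significance(d, "alpha[g]").excludes_zero


class TestSerialization:
    def test_long_frame_and_summary(self, d15n_draws):
        frame = d15n_draws.to_frame()
        assert set(frame.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(frame) == d15n_draws.n_draws * len(d15n_draws.parameter_names())
        summ = d15n_draws.summary()
        sigma = summ[summ["parameter"] == "sigma"].iloc[0]
        assert sigma["q2.5"] < sigma["q50"] < sigma["q97.5"]
        assert sigma["rhat"] < 1.05
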