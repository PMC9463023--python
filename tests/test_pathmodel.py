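"""Path-analysis MCMC: pathway structure, sampler correctness, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from colonywatch.errors import ConfigurationError, DataError
from colonywatch.pathmodel import (EdgeSpec, MCMCConfig, PathwaySpec,
                                   PriorSpec, build_pathways,
                                   effective_sample_size, fit_all_pathways,
                                   gelman_rubin, mcmc_fit, pathway_estimate,
                                   sample_prior, standardize_path_data)

TINY = MCMCConfig(chains=3, iterations=4000, thin=1, burn_in=1000, seed=0)


def make_path_data(seed=5, n=50, n_sites=17, b_qr=-0.5, b_rf=-0.3,
                   b_fl=-0.4, b_ls=-0.6):
    rng = np.random.default_rng(seed)
    site = np.repeat([f"s{i:02d}" for i in range(n_sites)],
                     -(-n // n_sites))[:n]
    q = rng.normal(size=n_sites)
    qrow = np.array([q[int(s[1:])] for s in site])
    ret = b_qr * qrow + rng.normal(0, 0.9, n)
    freq = 0.5 * qrow + b_rf * ret + rng.normal(0, 0.8, n)
    lay = b_fl * freq + rng.normal(0, 0.9, n)
    succ = (rng.random(n) < expit(0.6 + b_ls * lay)).astype(int)
    df = pd.DataFrame({"site_id": site, "quality": qrow, "return_day": ret,
                       "occ_freq": freq, "lay_date": lay, "success": succ})
    return standardize_path_data(df)


class TestPathwayStructure:
    def test_exactly_five_pathways(self):
        assert len(build_pathways()) == 5

    def test_first_pathway_is_single_quality_to_success_edge(self):
        p1 = build_pathways()[0]
        assert p1.edges == (EdgeSpec("success", "quality", "bernoulli"),)

    def test_fifth_pathway_full_chain(self):
        p5 = build_pathways()[4]
        assert p5.chain == ("quality", "return_day", "occ_freq", "lay_date",
                            "success")
        assert [e.family for e in p5.edges] == ["gaussian"] * 3 + [
            "bernoulli"]

    def test_pathway_must_start_at_quality_and_end_at_success(self):
        with pytest.raises(ConfigurationError):
            PathwaySpec("bad", ("return_day", "success"), ())

    def test_success_endpoint_stays_binary(self):
        df = make_path_data()
        assert set(df["success"].unique()) <= {0, 1}
        for c in ("quality", "return_day", "occ_freq", "lay_date"):
            assert df[c].mean() == pytest.approx(0, abs=1e-9)
            assert df[c].std(ddof=1) == pytest.approx(1, abs=1e-9)


class TestMCMCConfig:
    def test_canonical_schedule(self):
        c = MCMCConfig()
        assert (c.chains, c.iterations, c.thin, c.burn_in) == (
            3, 200_000, 3, 15_000)

    def test_burn_in_must_precede_end(self):
        with pytest.raises(ConfigurationError):
            MCMCConfig(iterations=1000, burn_in=2000)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        x = np.random.default_rng(0).normal(size=1000)
        chains = np.stack([x, x, x])
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=1e-3)

    def test_same_distribution_chains_below_105(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 2000),
                           rng.normal(10, 1, 2000)])
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))

    def test_agrees_with_arviz_on_mixing_chains(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 4000)) + 0.05 * np.cumsum(
            rng.normal(size=(3, 4000)), axis=1) / 60
        mine = gelman_rubin(chains)
        theirs = float(az.rhat(az.from_dict({"x": chains}))["x"])
        assert mine == pytest.approx(theirs, abs=0.05)


class TestEffectiveSampleSize:
    def test_iid_draws_ess_close_to_n(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(3, 5000))
        ess = effective_sample_size(chains)
        assert ess == pytest.approx(15_000, rel=0.10)

    def test_ar1_matches_analytic_autocorrelation_time(self):
        rho = 0.9
        rng = np.random.default_rng(5)
        n = 60_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        ess = effective_sample_size(x[None, :])
        expected = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.25)

    def test_thinning_raises_ess_per_draw(self):
        rho = 0.9
        rng = np.random.default_rng(6)
        n = 30_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        full = effective_sample_size(x[None, :]) / n
        thinned = effective_sample_size(x[None, ::3]) / (n / 3)
        assert thinned > full

    def test_constant_chain_undefined(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.ones((2, 100)))

    def test_agrees_with_arviz_order_of_magnitude(self):
        import arviz as az

        rng = np.random.default_rng(7)
        chains = rng.normal(size=(3, 3000))
        mine = effective_sample_size(chains)
        theirs = float(az.ess(az.from_dict({"x": chains}))["x"])
        assert mine == pytest.approx(theirs, rel=0.15)


class TestGaussianEdgeConjugacy:
    def test_posterior_mean_matches_closed_form(self):
        """Conjugate check with precisions pinned by strong data.

        With known-precision normal likelihood the exact posterior of β is
        N(m, v) with v = (τ x'x + τ0)⁻¹; the sampler's Gibbs draws must
        reproduce that mean within Monte-Carlo error.
        """
        data = make_path_data(seed=11, n=200, n_sites=200)  # 1 obs/site
        post = mcmc_fit(build_pathways()[1], data, config=TINY)
        draws = post.draws["return_day~quality.beta"]
        x = data["quality"].to_numpy()
        y = data["return_day"].to_numpy()
        # closed-form conjugate posterior conditional on tau_e ~ its
        # posterior mean and no site effect (1 obs per site: site effect
        # and residual are exchangeable; their sum is what is identified)
        tau = 1.0 / np.var(y - x * (x @ y / (x @ x)))
        prior_prec = PriorSpec().coef_precision
        v = 1.0 / (tau * (x @ x) + prior_prec)
        m = v * tau * (x @ y)
        mc_se = draws.std() / np.sqrt(effective_sample_size(draws))
        assert draws.mean() == pytest.approx(m, abs=3 * mc_se + 0.02)

    def test_bernoulli_edge_mode_near_logistic_ml_at_large_n(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 5000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 - 0.7 * x)).astype(int)
        df = pd.DataFrame({
            "site_id": [f"s{i % 40:02d}" for i in range(n)],
            "quality": x, "success": y,
        })
        df["quality"] = (df.quality - df.quality.mean()) / df.quality.std(
            ddof=1)
        post = mcmc_fit(build_pathways()[0], df, config=TINY)
        beta = post.draws["success~quality.beta"].mean()
        ml = sm.GLM(y, sm.add_constant(df["quality"]),
                    family=sm.families.Binomial()).fit().params.iloc[1]
        assert beta == pytest.approx(ml, abs=0.05)


class TestPriorOnlySampling:
    def test_prior_moments_reproduced(self):
        draws = sample_prior(config=MCMCConfig(chains=3, iterations=9000,
                                               thin=1, burn_in=1000,
                                               seed=3))
        pr = PriorSpec()
        sd = 1 / np.sqrt(pr.coef_precision)  # 31.6
        for par in ("alpha", "beta"):
            flat = draws[par].ravel()
            assert flat.mean() == pytest.approx(0, abs=4 * sd
                                                / np.sqrt(flat.size / 4))
            assert flat.std() == pytest.approx(sd, rel=0.10)
        # Gamma(0.001, 0.001) has mean 1
        tau = draws["tau_resid"].ravel()
        assert tau.mean() == pytest.approx(1.0, abs=4 * tau.std()
                                           / np.sqrt(tau.size / 10))


class TestPathwayEstimate:
    def test_single_edge_pathway_equals_edge_summary(self):
        data = make_path_data(seed=13)
        post = mcmc_fit(build_pathways()[0], data, config=TINY)
        edge = post.draws["success~quality.beta"]
        path = post.pathway_draws()
        np.testing.assert_array_equal(edge, path)
        s = post.summary()
        assert s["estimate"] == pytest.approx(float(edge.mean()))

    def test_product_rule_recovers_product_of_generating_edges(self):
        # edges 0.5 and 0.4 -> pathway estimate near 0.20 at large n
        rng = np.random.default_rng(14)
        n = 4000
        site = [f"s{i % 50:02d}" for i in range(n)]
        q = rng.normal(size=n)
        ret = 0.5 * q + rng.normal(0, np.sqrt(1 - 0.25), n)
        succ = (rng.random(n) < expit(0.4 * ret)).astype(int)
        df = pd.DataFrame({"site_id": site, "quality": q,
                           "return_day": ret, "success": succ})
        for c in ("quality", "return_day"):
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
        post = mcmc_fit(build_pathways()[1], df, config=TINY)
        est = post.summary()["estimate"]
        # logit edge ML at this n has sd ~0.04; product near 0.5*0.4
        assert est == pytest.approx(0.5 * 0.4, abs=0.05)

    def test_pct_same_sign_of_symmetric_posterior_near_50(self):
        rng = np.random.default_rng(15)
        out = pathway_estimate(rng.normal(size=(3, 20_000)))
        assert out["pct_same_sign"] == pytest.approx(50, abs=2)

    def test_pct_same_sign_bounds(self):
        out = pathway_estimate(np.abs(np.random.default_rng(16).normal(
            size=(3, 1000))) + 0.1)
        assert out["pct_same_sign"] == 100.0
        assert out["ci_lower"] <= out["estimate"] <= out["ci_upper"]


class TestSamplerContracts:
    def test_seeded_determinism(self):
        data = make_path_data(seed=17)
        a = mcmc_fit(build_pathways()[1], data, config=TINY)
        b = mcmc_fit(build_pathways()[1], data, config=TINY)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_fit_all_matches_individual_fits(self):
        data = make_path_data(seed=18)
        together = fit_all_pathways(data, config=TINY)
        alone = mcmc_fit(build_pathways()[2], data, config=TINY)
        np.testing.assert_array_equal(together[2].pathway_draws(),
                                      alone.pathway_draws())

    def test_missing_values_rejected(self):
        data = make_path_data(seed=19)
        data.loc[0, "quality"] = np.nan
        with pytest.raises(DataError):
            mcmc_fit(build_pathways()[0], data)

    def test_posterior_sd_shrinks_like_root_n(self):
        small = make_path_data(seed=20, n=50, n_sites=17)
        big = make_path_data(seed=20, n=500, n_sites=170)
        p_small = mcmc_fit(build_pathways()[1], small, config=TINY)
        p_big = mcmc_fit(build_pathways()[1], big, config=TINY)
        r = (p_small.draws["return_day~quality.beta"].std()
             / p_big.draws["return_day~quality.beta"].std())
        assert r == pytest.approx(np.sqrt(10), rel=0.30)

    def test_zero_signal_credible_intervals_cover_zero(self):
        covered = 0
        reps = 12
        for rep in range(reps):
            rng = np.random.default_rng(600 + rep)
            n = 60
            df = pd.DataFrame({
                "site_id": [f"s{i % 20:02d}" for i in range(n)],
                "quality": rng.normal(size=n),
                "return_day": rng.normal(size=n),
            })
            df["success"] = rng.integers(0, 2, size=n)
            for c in ("quality", "return_day"):
                df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
            cfg = MCMCConfig(chains=3, iterations=3000, thin=1,
                             burn_in=1000, seed=rep)
            post = mcmc_fit(build_pathways()[1], df, config=cfg)
            d = post.draws["return_day~quality.beta"].ravel()
            lo, hi = np.percentile(d, [2.5, 97.5])
            covered += lo <= 0 <= hi
        assert covered >= 0.9 * reps - 1e-9
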