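"""Mixed-model engine: collapse identities, oracles, selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from colonywatch.errors import DegenerateGroupError
from colonywatch.glmm import (ModelSpec, RandomTerm, _apply_aic_rule,
                              _MixedProblem, aic_select, candidate_specs,
                              collinearity_screen, confint_fixed, fit_mixed,
                              ks_normality, r_squared_nakagawa,
                              random_structure_select)


def _gauss_data(seed=1, n=80, n_groups=8, sd_re=1.5):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, size=n)
    x = rng.normal(size=n)
    re = rng.normal(0, sd_re, size=n_groups)
    y = 1.0 + 2.0 * x + re[g] + rng.normal(size=n)
    return pd.DataFrame({"x": x, "g": g.astype(str), "y": y})


class TestCollapseIdentities:
    def test_gaussian_without_random_terms_equals_least_squares(self):
        df = _gauss_data(sd_re=0.0)
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),)), df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta_ls, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.estimates, beta_ls, rtol=1e-10)

    def test_bernoulli_without_random_variance_equals_logistic_ml(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.4 + 0.9 * x)).astype(int)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_mixed(ModelSpec("y", "bernoulli", fixed=(("x",),)), df)
        import statsmodels.api as sm

        oracle = sm.GLM(y, sm.add_constant(x),
                        family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.estimates, oracle.params, atol=1e-6)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)


class TestAgainstStatsmodelsMixedLM:
    def test_gaussian_random_intercept_ml(self):
        import statsmodels.formula.api as smf

        df = _gauss_data()
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df)
        oracle = smf.mixedlm("y ~ x", df, groups="g").fit(reml=False)
        np.testing.assert_allclose(fit.estimates, oracle.fe_params,
                                   atol=1e-5)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
        np.testing.assert_allclose(fit.se, oracle.bse_fe, atol=2e-3)

    def test_gaussian_random_intercept_reml(self):
        import statsmodels.formula.api as smf

        df = _gauss_data(seed=5)
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df, reml=True)
        oracle = smf.mixedlm("y ~ x", df, groups="g").fit(reml=True)
        np.testing.assert_allclose(fit.estimates, oracle.fe_params,
                                   atol=1e-5)
        np.testing.assert_allclose(fit.se, oracle.bse_fe, atol=2e-3)


def adaptive_gh_loglik(prob, beta, sd, nodes=200):
    """Brute-force marginal log-likelihood: mode-centered 200-node GH."""
    from scipy.optimize import minimize_scalar

    xq, wq = np.polynomial.hermite.hermgauss(nodes)
    eta_fix = prob.X @ beta
    y, m = prob.y, prob.trials
    ll = prob.ll_const
    codes = prob.blocks[0].codes
    for gi in range(prob.blocks[0].n_groups):
        mask = codes == gi
        yg, mg, ef = y[mask], m[mask], eta_fix[mask]

        def negj(u):
            eta = ef + u
            return -(np.sum(yg * eta - mg * np.logaddexp(0, eta))
                     - 0.5 * u * u / sd ** 2)

        r = minimize_scalar(negj, bounds=(-10, 10), method="bounded",
                            options={"xatol": 1e-12})
        uhat = r.x
        p = expit(ef + uhat)
        h = np.sum(mg * p * (1 - p)) + 1 / sd ** 2
        s = 1 / np.sqrt(h)
        us = uhat + np.sqrt(2) * s * xq
        etas = ef[None, :] + us[:, None]
        llg = ((yg[None, :] * etas
                - mg[None, :] * np.logaddexp(0, etas)).sum(axis=1)
               - 0.5 * us ** 2 / sd ** 2 + xq ** 2)
        mx = llg.max()
        ll += np.log(np.sqrt(2) * s
                     * np.sum(wq * np.exp(llg - mx))
                     / np.sqrt(2 * np.pi) / sd) + mx
    return ll


def _binom_problem(trials, seed=7, n=20, n_groups=5):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n // n_groups)
    x = rng.normal(size=n)
    u = rng.normal(0, 0.4, size=n_groups)
    m = np.full(n, trials)
    y = rng.binomial(m, expit(0.2 + 0.6 * x + u[g]))
    df = pd.DataFrame({"y": y, "m": m, "x": x, "g": g.astype(str)})
    spec = ModelSpec("y", "binomial", fixed=(("x",),),
                     random=(RandomTerm("g"),), trials="m")
    return _MixedProblem(spec, df)


FIXED_POINTS = [(0.2, 0.6, 0.4), (0.0, 0.0, 0.3), (0.3, -0.2, 0.5),
                (0.2, 0.6, 0.15), (0.1, 0.3, 0.6)]


class TestLaplaceQuadratureOracle:
    def test_realistic_trial_counts_agree_to_1e4(self):
        prob = _binom_problem(trials=150)
        for b0, b1, sd in FIXED_POINTS:
            beta = np.array([b0, b1])
            lap = -0.5 * prob.laplace_deviance(np.array([np.log(sd)]),
                                               offset=prob.X @ beta,
                                               x_cols=[])
            gh = adaptive_gh_loglik(prob, beta, sd)
            assert abs(lap - gh) / abs(gh) < 1e-4


class TestConfidenceIntervals:
    def test_wald_is_estimate_pm_196_se(self):
        df = _gauss_data()
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df)
        ci = confint_fixed(fit, method="wald")
        z = 1.959963984540054
        for j, row in ci.iterrows():
            assert row["lower"] == pytest.approx(
                fit.estimates[j] - z * fit.se[j])
            assert row["upper"] == pytest.approx(
                fit.estimates[j] + z * fit.se[j])

    def test_significance_flag_follows_zero_crossing(self):
        df = _gauss_data()
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df)
        ci = confint_fixed(fit, method="wald").set_index("term")
        assert bool(ci.loc["x", "significant"])  # strong true effect
        assert ci.loc["x", "lower"] > 0

    def test_profile_interval_brackets_wald_closely_in_gaussian(self):
        df = _gauss_data(n=150)
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df)
        prof = confint_fixed(fit, method="profile").set_index("term")
        wald = confint_fixed(fit, method="wald").set_index("term")
        # large-n: profile and Wald agree to a few percent of the SE
        for term in ("x",):
            assert prof.loc[term, "lower"] == pytest.approx(
                wald.loc[term, "lower"], abs=0.25 * fit.se[1])
            assert prof.loc[term, "upper"] == pytest.approx(
                wald.loc[term, "upper"], abs=0.25 * fit.se[1])
            assert prof.loc[term, "method"] == "profile"


class TestAICRule:
    def test_clear_gap_selects_lowest(self):
        entries = [{"name": "A", "aic": 100.0, "k": 3, "order": ("a",)},
                   {"name": "B", "aic": 103.0, "k": 4, "order": ("a", "b")}]
        chosen, rule = _apply_aic_rule(entries)
        assert chosen["name"] == "A"
        assert ">2" in rule

    def test_close_aic_prefers_parsimony(self):
        entries = [{"name": "B", "aic": 100.0, "k": 4, "order": ("a", "b")},
                   {"name": "A", "aic": 101.5, "k": 3, "order": ("a",)}]
        chosen, rule = _apply_aic_rule(entries)
        assert chosen["name"] == "A"
        assert "parsimonious" in rule

    def test_identical_aic_tie_broken_lexicographically(self):
        entries = [{"name": "B", "aic": 100.0, "k": 3, "order": ("b",)},
                   {"name": "A", "aic": 100.0, "k": 3, "order": ("a",)}]
        chosen, _ = _apply_aic_rule(entries)
        assert chosen["name"] == "A"

    def test_candidate_specs_respect_marginality(self):
        spec = ModelSpec("y", "gaussian",
                         fixed=(("a",), ("b",), ("a", "b")))
        cands = candidate_specs(spec)
        assert len(cands) == 5  # {}, {a}, {b}, {a,b}, {a,b,ab}
        for c in cands:
            mains = {t[0] for t in c.fixed if len(t) == 1}
            assert all(set(t) <= mains for t in c.fixed if len(t) > 1)

    def test_selection_recovers_single_true_effect(self):
        # 3 covariates, one 1-SD effect, n=120: the true fixed structure
        # must win in at least 80% of seeded replicates
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            n = 120
            df = pd.DataFrame({
                "x1": rng.normal(size=n), "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            })
            df["y"] = 1.0 * df.x1 + rng.normal(size=n)
            base = ModelSpec("y", "gaussian",
                             fixed=(("x1",), ("x2",), ("x3",)))
            sel = aic_select(candidate_specs(base), df)
            hits += sel.chosen.spec.fixed == (("x1",),)
        assert hits / reps >= 0.80

    def test_candidates_with_missing_data_share_identical_rows(self):
        # the null model could use every row; the rule requires all
        # candidates to be fitted on the complete-case intersection
        df = _gauss_data()
        df.loc[0, "x"] = np.nan
        c1 = ModelSpec("y", "gaussian", fixed=())
        c2 = ModelSpec("y", "gaussian", fixed=(("x",),))
        sel = aic_select([c1, c2], df)
        ns = {f.n for f in sel.fits.values()}
        assert ns == {len(df) - 1}


class TestRandomStructureSelection:
    def test_intercept_truth_recovered_in_majority(self):
        wins = 0
        reps = 10
        for rep in range(reps):
            df = _gauss_data(seed=500 + rep, n=240, n_groups=12, sd_re=2.0)
            spec = ModelSpec("y", "gaussian", fixed=(("x",),),
                             random=(RandomTerm("g"),))
            sel = random_structure_select(spec, df, group="g", slope="x")
            wins += sel.chosen.spec.random[-1].structure == "intercept"
        assert wins > reps / 2

    def test_zero_variance_truth_flags_boundary(self):
        df = _gauss_data(seed=42, sd_re=0.0)
        spec = ModelSpec("y", "gaussian", fixed=(("x",),),
                         random=(RandomTerm("g"),))
        fit = fit_mixed(spec, df)
        assert fit.boundary


class TestFitStatistics:
    def test_aic_identity(self):
        df = _gauss_data()
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),),
                                  random=(RandomTerm("g"),)), df)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)

    def test_adding_useless_term_never_lowers_loglik(self):
        df = _gauss_data()
        df["junk"] = np.random.default_rng(9).normal(size=len(df))
        small = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),)), df)
        big = fit_mixed(ModelSpec("y", "gaussian",
                                  fixed=(("x",), ("junk",))), df)
        assert big.loglik >= small.loglik - 1e-8
        assert big.aic >= small.aic - 2 + 1e-10 - 2e-8

    def test_r2_zero_random_variance_collapses(self):
        df = _gauss_data(sd_re=0.0)
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),)), df)
        marg, cond = r_squared_nakagawa(fit)
        assert marg == pytest.approx(cond)

    def test_r2_null_fixed_model_is_zero(self):
        df = _gauss_data()
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(),
                                  random=(RandomTerm("g"),)), df)
        marg, cond = r_squared_nakagawa(fit)
        assert marg == pytest.approx(0.0, abs=1e-10)
        assert cond >= marg

    def test_r2_single_level_gaussian_equals_classical(self):
        df = _gauss_data(sd_re=0.0)
        fit = fit_mixed(ModelSpec("y", "gaussian", fixed=(("x",),)), df)
        marg, _ = r_squared_nakagawa(fit)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        yhat = X @ fit.estimates
        y = df["y"].to_numpy()
        ssr = np.sum((y - yhat) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        # population-variance convention on both terms
        classical = np.var(yhat) / (np.var(yhat) + ssr / len(y))
        assert marg == pytest.approx(classical, abs=1e-8)

    def test_conditional_at_least_marginal_everywhere(self, analysis_table):
        spec = ModelSpec("return_day", "gaussian", fixed=(("quality_z",),),
                         random=(RandomTerm("site_id"),))
        fit = fit_mixed(spec, analysis_table)
        marg, cond = r_squared_nakagawa(fit)
        assert 0 <= marg <= cond <= 1


class TestKSNormality:
    def test_exact_normal_quantiles_give_small_d(self):
        from scipy.stats import norm

        q = norm.ppf((np.arange(1, 201) - 0.5) / 200)
        out = ks_normality(q)
        assert out["D"] < 0.02

    def test_matches_direct_enumeration_on_ten_points(self):
        from scipy.stats import norm

        v = np.array([-1.3, -0.8, -0.4, -0.1, 0.05, 0.3, 0.6, 0.9, 1.4,
                      2.0])
        out = ks_normality(v)
        z = np.sort((v - v.mean()) / v.std(ddof=1))
        cdf = norm.cdf(z)
        n = len(v)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert out["D"] == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_uniform_sample_rejected_in_majority(self):
        # moment-estimating the parameters makes the plain KS p-value
        # conservative, so a clearly non-normal shape needs n ~ 1000 for
        # the naive test to reject reliably
        rejections = 0
        for rep in range(9):
            rng = np.random.default_rng(100 + rep)
            out = ks_normality(rng.random(1000))
            rejections += out["p"] < 0.05
        assert rejections > 4

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateGroupError):
            ks_normality(np.ones(10))


class TestCollinearityScreen:
    def test_flag_set_iff_above_cutoff(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        df = pd.DataFrame({"a": a, "b": a + 0.1 * rng.normal(size=300),
                           "c": rng.normal(size=300)})
        out = collinearity_screen(df, ["a", "b", "c"])
        flags = out.set_index(["var_a", "var_b"])["flagged"]
        assert bool(flags.loc[("a", "b")])
        assert not bool(flags.loc[("a", "c")])


class TestStandardizationIdempotence:
    def test_fit_on_prestandardized_covariate_reproduces_z_estimates(self):
        df = _gauss_data(n=200)
        df["xz"] = (df.x - df.x.mean()) / df.x.std(ddof=1)
        f1 = fit_mixed(ModelSpec("y", "gaussian", fixed=(("xz",),),
                                 random=(RandomTerm("g"),)), df)
        df2 = df.assign(xz=(df.xz - df.xz.mean()) / df.xz.std(ddof=1))
        f2 = fit_mixed(ModelSpec("y", "gaussian", fixed=(("xz",),),
                                 random=(RandomTerm("g"),)), df2)
        np.testing.assert_allclose(f1.estimates, f2.estimates, atol=1e-8)
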