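"""Mixed models, AIC selection, VIF, mediation, Spearman matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcale import (ModelSpec, fit_lmm, mediate, pooled_term_fdr,
                      spearman_matrix, stepwise_aic, vif)


def make_table(n_sub=30, n_trial=40, beta=0.5, intercept_sd=0.5,
               noise_sd=0.5, seed=0, extra_noise_terms=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        u = rng.normal(0, intercept_sd)
        x = rng.normal(0, 1, n_trial)
        y = beta * x + u + rng.normal(0, noise_sd, n_trial)
        for i in range(n_trial):
            row = dict(participant=f"s{s:02d}", x=x[i], y=y[i])
            for k in range(extra_noise_terms):
                row[f"z{k}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_response_equals_predictor(self):
        t = make_table(seed=1)
        t["y"] = t["x"]
        fit = fit_lmm(t, "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(1.0, abs=1e-6)
        resid_var = np.var(t.y - fit.coefficients["Intercept"]
                           - fit.coefficients["x"] * t.x)
        assert resid_var == pytest.approx(0.0, abs=1e-10)

    def test_slope_recovery(self):
        fit = fit_lmm(make_table(beta=0.5, seed=2), "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.5, abs=0.05)
        assert fit.p_values["x"] < 1e-6

    def test_random_intercept_variance_recovered(self):
        t = make_table(n_sub=60, n_trial=60, beta=0.0, intercept_sd=1.0,
                       noise_sd=0.5, seed=3)
        fit = fit_lmm(t, "y", ["x"])
        assert abs(fit.coefficients["x"]) < 0.05
        re_var = float(np.asarray(fit._result.cov_re)[0, 0])
        assert re_var == pytest.approx(1.0, rel=0.35)

    def test_missing_rows_reported(self):
        t = make_table(seed=4)
        t.loc[t.index[:17], "x"] = np.nan
        fit = fit_lmm(t, "y", ["x"])
        assert fit.n_dropped == 17

    def test_single_group_rejected(self):
        t = make_table(n_sub=1, seed=5)
        with pytest.raises(ValueError):
            fit_lmm(t, "y", ["x"])


class TestStepwise:
    def test_true_predictor_selected_among_noise(self):
        hits = 0
        for seed in range(10):
            t = make_table(beta=0.5, seed=seed, extra_noise_terms=5)
            spec = ModelSpec(response="y",
                             candidate_terms=["x"] + [f"z{k}" for k in range(5)])
            fit = stepwise_aic(t, spec)
            hits += "x" in fit.included_terms
        assert hits >= 9

    def test_no_signal_pool_selects_few(self):
        counts = []
        for seed in range(6):
            t = make_table(beta=0.0, seed=100 + seed, extra_noise_terms=5)
            spec = ModelSpec(response="y",
                             candidate_terms=[f"z{k}" for k in range(5)])
            counts.append(len(stepwise_aic(t, spec).included_terms))
        assert np.median(counts) <= 1

    def test_deterministic_given_data(self):
        t = make_table(beta=0.4, seed=7, extra_noise_terms=3)
        spec = ModelSpec(response="y",
                         candidate_terms=["x", "z0", "z1", "z2"])
        a = stepwise_aic(t, spec)
        b = stepwise_aic(t, spec)
        assert a.included_terms == b.included_terms
        assert a.aic == b.aic

    def test_response_excluded_from_candidates(self):
        with pytest.raises(ValueError):
            ModelSpec(response="y", candidate_terms=["y", "x"])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 400
        X = pd.DataFrame(dict(a=np.tile([1.0, -1.0], n // 2),
                              b=np.repeat([1.0, -1.0], n // 2)))
        np.testing.assert_allclose(vif(X).to_numpy(), 1.0, atol=1e-9)

    def test_near_collinear_vif_explodes(self, rng):
        x1 = rng.normal(0, 1, 500)
        X = pd.DataFrame(dict(x1=x1, x2=x1 + rng.normal(0, 0.01, 500)))
        assert vif(X)["x2"] > 100

    def test_three_predictor_toy_matches_direct_regression(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=list("abc"))
        X["a"] += 0.7 * X["b"]
        out = vif(X)
        import statsmodels.api as sm
        for col in X.columns:
            r2 = sm.OLS(X[col], sm.add_constant(X.drop(columns=[col]))).fit().rsquared
            assert out[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


def make_mediation_table(n_sub=40, n_trial=48, a=0.6, b=0.5, direct=0.0,
                         seed=0):
    """Planted-mediation data with independent participant intercepts in the
    mediator and outcome equations (keeps the mediator exogenous in the
    outcome model, so the true indirect effect is exactly a*b)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        u_m = rng.normal(0, 0.5)
        u_y = rng.normal(0, 0.5)
        x = rng.normal(0, 1, n_trial)
        m = a * x + u_m + rng.normal(0, 0.5, n_trial)
        y = b * m + direct * x + u_y + rng.normal(0, 0.5, n_trial)
        rows += [dict(participant=f"s{s:02d}", x=x[i], m=m[i], y=y[i])
                 for i in range(n_trial)]
    return pd.DataFrame(rows)


class TestMediation:
    def test_full_mediation_recovered(self):
        t = make_mediation_table(a=0.6, b=0.5, direct=0.0, seed=1)
        res = mediate(t, "x", "m", "y", n_draws=3000, seed=2)
        assert res.assessed
        assert res.acme == pytest.approx(0.30, abs=0.05)
        assert res.ade_ci[0] < 0.0 < res.ade_ci[1]
        assert res.acme_ci[0] <= res.acme <= res.acme_ci[1]

    def test_independent_mediator_ci_covers_zero(self):
        t = make_mediation_table(a=0.0, b=0.0, direct=0.5, seed=3)
        res = mediate(t, "x", "m", "y", n_draws=2000, seed=4)
        assert not res.assessed
        assert res.acme_ci[0] <= 0.0 <= res.acme_ci[1]

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n_sub in (10, 40, 160):
            t = make_mediation_table(n_sub=n_sub, seed=5)
            res = mediate(t, "x", "m", "y", n_draws=2000, seed=6)
            widths.append(res.acme_ci[1] - res.acme_ci[0])
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): quadrupling n halves the width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame(dict(a=rng.normal(0, 1, 30)))
        df["b"] = df["a"]
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        df = pd.DataFrame(dict(a=rng.normal(0, 1, 30)))
        df["b"] = np.exp(df["a"])
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_five_point_toy_matches_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 9.0, 2.5, 6.0])
        df = pd.DataFrame(dict(x=x, y=y))
        rho, _ = spearman_matrix(df)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(expected)

    def test_pooled_fdr_assigns_q_per_term(self):
        fits = [fit_lmm(make_table(beta=0.5, seed=s), "y", ["x"])
                for s in (11, 12)]
        fits = pooled_term_fdr(fits)
        for f in fits:
            assert np.isfinite(f.fdr_q["x"])
            assert f.fdr_q["x"] >= f.p_values["x"]
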