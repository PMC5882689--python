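"""Conditional-logit likelihood, Newton fitting, and backward selection.

Oracles: finite differences for the gradient/Hessian, direct numerical
maximization of the enumerated likelihood, a 1-D grid search, reduction
to paired logistic regression, and statsmodels' ConditionalLogit.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import oceanssf as o
from oceanssf.ssf_model import _stratum_layout, build_design, clogit_loglik

from conftest import TERMS, MODEL_VARS, make_random_strata


def layout(df):
    return _stratum_layout(df["stratum_id"].to_numpy(), df["is_case"].to_numpy(bool))


def enumerated_loglik(beta, df, terms):
    """Independent oracle: per-stratum softmax probability of the case, summed."""
    total = 0.0
    for _, grp in df.groupby("stratum_id"):
        eta = build_design(grp, terms) @ beta
        p = np.exp(eta - eta.max())
        p /= p.sum()
        total += np.log(p[grp["is_case"].to_numpy(bool)][0])
    return total


class TestLoglik:
    def test_null_loglik_closed_form(self):
        rng = np.random.default_rng(0)
        df = make_random_strata(rng, n_strata=7, max_size=5, n_terms=2)
        order, starts, counts, case_pos = layout(df)
        X = build_design(df, ["x0", "x1"])[order]
        ll, grad, _ = clogit_loglik(np.zeros(2), X, starts, counts, case_pos)
        sizes = df.groupby("stratum_id").size().to_numpy()
        assert ll == pytest.approx(-np.sum(np.log(sizes)), rel=1e-12)

    def test_null_loglik_paper_scale(self):
        # 61 strata of 1 case + 100 alternatives: l(0) = -61 ln 101
        rng = np.random.default_rng(1)
        rows = []
        for s in range(61):
            for j in range(101):
                rows.append(dict(stratum_id=s, is_case=j == 0, x0=rng.normal()))
        df = pd.DataFrame(rows)
        order, starts, counts, case_pos = layout(df)
        X = build_design(df, ["x0"])[order]
        ll, _, _ = clogit_loglik(np.zeros(1), X, starts, counts, case_pos)
        assert ll == pytest.approx(-61 * np.log(101), rel=1e-12)
        assert ll == pytest.approx(-281.522, abs=5e-4)

    def test_gradient_at_zero_is_case_minus_stratum_mean(self):
        rng = np.random.default_rng(2)
        df = make_random_strata(rng, n_strata=5, n_terms=2)
        order, starts, counts, case_pos = layout(df)
        X = build_design(df, ["x0", "x1"])[order]
        _, grad, _ = clogit_loglik(np.zeros(2), X, starts, counts, case_pos)
        expect = np.zeros(2)
        for _, grp in df.groupby("stratum_id"):
            Xg = build_design(grp, ["x0", "x1"])
            expect += Xg[grp["is_case"].to_numpy(bool)][0] - Xg.mean(axis=0)
        np.testing.assert_allclose(grad, expect, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_hessian_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        df = make_random_strata(rng, n_strata=6, n_terms=3)
        order, starts, counts, case_pos = layout(df)
        X = build_design(df, ["x0", "x1", "x2"])[order]
        beta = rng.normal(0, 0.5, 3)
        ll, grad, H = clogit_loglik(beta, X, starts, counts, case_pos)
        eps = 1e-6
        for k in range(3):
            d = np.zeros(3)
            d[k] = eps
            lp, gp, _ = clogit_loglik(beta + d, X, starts, counts, case_pos)
            lm, gm, _ = clogit_loglik(beta - d, X, starts, counts, case_pos)
            assert grad[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)
            np.testing.assert_allclose(H[:, k], (gp - gm) / (2 * eps), atol=1e-5)

    def test_stratum_without_case_rejected(self):
        df = pd.DataFrame(
            dict(stratum_id=[0, 0, 1, 1], is_case=[True, False, False, False], x0=[1.0, 2, 3, 4])
        )
        with pytest.raises(ValueError, match="1"):
            o.fit_clogit(df, ["x0"])


class TestFitting:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumerated_likelihood_maximum(self, seed):
        rng = np.random.default_rng(seed)
        n_terms = int(rng.integers(1, 4))
        # 10 strata of 1 case + 5 controls keeps the problem identifiable,
        # so both optimizers land on the same well-curved maximum
        df = make_random_strata(
            rng, n_strata=10, min_size=6, max_size=6, n_terms=n_terms,
            beta=rng.normal(0, 0.5, n_terms),
        )
        terms = [f"x{k}" for k in range(n_terms)]
        fit = o.fit_clogit(df, terms)
        res = optimize.minimize(
            lambda b: -enumerated_loglik(b, df, terms),
            np.zeros(n_terms), method="BFGS", jac="3-point",
            options=dict(gtol=1e-10, maxiter=500),
        )
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-5)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_one_dimensional_grid_search_oracle(self):
        df = pd.DataFrame(
            dict(
                stratum_id=[0, 0, 1, 1],
                is_case=[True, False, True, False],
                x0=[1.0, 0.0, 0.0, 1.0],
            )
        )
        fit = o.fit_clogit(df, ["x0"])
        grid = np.linspace(-3, 3, 600_001)
        ll = np.log(1 / (1 + np.exp(-grid))) + np.log(1 / (1 + np.exp(grid)))
        best = grid[np.argmax(ll)]
        assert fit.beta[0] == pytest.approx(best, abs=1e-5)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-6)  # symmetric design

    def test_pairs_reduce_to_difference_logistic_regression(self):
        # strata of size 2: clogit == logistic regression (no intercept) on
        # within-stratum differences case-minus-control
        rng = np.random.default_rng(3)
        df = make_random_strata(rng, n_strata=40, max_size=2, n_terms=2, beta=np.array([0.8, -0.5]))
        fit = o.fit_clogit(df, ["x0", "x1"])
        import statsmodels.api as sm

        diffs, ys = [], []
        for _, grp in df.groupby("stratum_id"):
            X = grp[["x0", "x1"]].to_numpy()
            case = grp["is_case"].to_numpy(bool)
            diffs.append(X[case][0] - X[~case][0])
            ys.append(1.0)
        lr = sm.Logit(np.array(ys), np.array(diffs)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, lr.params, atol=1e-5)

    def test_agrees_with_statsmodels_conditional_logit(self, scaled_strata):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        fit = o.fit_clogit(scaled_strata, TERMS)
        X = build_design(scaled_strata, TERMS)
        sm_fit = ConditionalLogit(
            scaled_strata["is_case"].astype(int).to_numpy(), X,
            groups=scaled_strata["stratum_id"].to_numpy(),
        ).fit(method="newton", disp=0)
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=2e-4)
        np.testing.assert_allclose(fit.se, sm_fit.bse, rtol=2e-3)
        assert fit.loglik >= sm_fit.llf - 1e-6

    def test_stratum_constant_shifts_are_absorbed(self):
        rng = np.random.default_rng(4)
        df = make_random_strata(rng, n_strata=12, n_terms=2, beta=np.array([1.0, -1.0]))
        fit = o.fit_clogit(df, ["x0", "x1"])
        shifted = df.copy()
        offsets = {s: rng.normal(0, 5) for s in df["stratum_id"].unique()}
        shifted["x0"] = shifted["x0"] + shifted["stratum_id"].map(offsets)
        fit2 = o.fit_clogit(shifted, ["x0", "x1"])
        np.testing.assert_allclose(fit2.beta, fit.beta, atol=1e-6)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_aic_identity_and_wald_p(self, scaled_strata):
        fit = o.fit_clogit(scaled_strata, TERMS)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(TERMS), abs=1e-9)
        from scipy import stats

        np.testing.assert_allclose(fit.p, 2 * stats.norm.sf(np.abs(fit.beta / fit.se)), rtol=1e-12)

    def test_separation_is_reported_not_fixed(self):
        # a perfectly separating covariate: case always has the largest value
        rows = []
        for s in range(8):
            rows += [
                dict(stratum_id=s, is_case=True, x0=1.0),
                dict(stratum_id=s, is_case=False, x0=0.0),
                dict(stratum_id=s, is_case=False, x0=-1.0),
            ]
        fit = o.fit_clogit(pd.DataFrame(rows), ["x0"])
        assert not fit.converged or fit.separation_suspected or fit.se[0] > 5

    def test_too_few_strata_rejected(self):
        rng = np.random.default_rng(5)
        df = make_random_strata(rng, n_strata=2, n_terms=3)
        with pytest.raises(ValueError, match="strata"):
            o.fit_clogit(df, ["x0", "x1", "x2"])

    def test_duplicate_terms_rejected(self):
        rng = np.random.default_rng(6)
        df = make_random_strata(rng, n_strata=5, n_terms=1)
        with pytest.raises(ValueError, match="duplicate"):
            o.fit_clogit(df, ["x0", "x0"])


class TestBackwardSelection:
    def simulated_with_noise(self, seed, n_strata=120, beta=(1.2, -0.8)):
        rng = np.random.default_rng(seed)
        df = make_random_strata(rng, n_strata=n_strata, max_size=8, n_terms=2, beta=np.array(beta))
        df["noise"] = rng.normal(size=len(df))
        return df

    def test_all_significant_keeps_full_model(self):
        df = self.simulated_with_noise(0)
        trace = o.backward_select(df, ["x0", "x1"])
        assert len(trace.fits) == 1
        assert trace.best.terms == ["x0", "x1"]

    def test_noise_term_dropped_first(self):
        dropped_first = 0
        n_rep = 50
        for seed in range(n_rep):
            df = self.simulated_with_noise(seed)
            trace = o.backward_select(df, ["x0", "x1", "noise"])
            if len(trace.dropped) > 1 and trace.dropped[1] == "noise":
                dropped_first += 1
        assert dropped_first >= int(0.9 * n_rep)

    def test_marginality_respected(self):
        rng = np.random.default_rng(7)
        df = make_random_strata(rng, n_strata=60, max_size=6, n_terms=2)
        trace = o.backward_select(df, ["x0", "x1", "x0:x1"])
        for fit in trace.fits:
            if "x0:x1" in fit.terms:
                assert "x0" in fit.terms and "x1" in fit.terms

    def test_best_is_lowest_aic(self, scaled_strata):
        trace = o.backward_select(scaled_strata, TERMS)
        assert trace.best.aic == pytest.approx(min(f.aic for f in trace.fits))
        table = trace.table()
        assert len(table) == len(trace.fits)
        assert table["aic"].iloc[0] == pytest.approx(trace.fits[0].aic)


def test_estimator_follows_sklearn_protocol():
    est = o.ConditionalLogitSSF(max_iter=25)
    assert est.get_params()["max_iter"] == 25
    est.set_params(max_iter=30)
    rng = np.random.default_rng(8)
    df = make_random_strata(rng, n_strata=10, n_terms=2, beta=np.array([1.0, 0.0]))
    X = df[["x0", "x1"]].to_numpy()
    est.fit(X, df["is_case"].to_numpy(), groups=df["stratum_id"].to_numpy())
    assert est.coef_.shape == (2,)
    assert est.decision_function(X).shape == (len(df),)
    with pytest.raises(ValueError):
        o.ConditionalLogitSSF().fit(X, df["is_case"].to_numpy())
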