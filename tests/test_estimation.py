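"""Weighted OLS, HC1 sandwich, Breusch-Pagan, percent effects, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ctmatch import estimation as est


def design(n=60, k=3, seed=0, het=False):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    sd = np.exp(X[:, 1]) if het else 1.0
    y = X @ beta + rng.normal(size=n) * sd
    w = rng.uniform(0.5, 2.0, size=n)
    return X, y, w, beta


class TestWeightedOLS:
    def test_noiseless_recovery(self):
        X, _, w, beta = design()
        res = est.weighted_ols(X, X @ beta, w)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_equal_weights_match_unweighted(self):
        X, y, _, _ = design(seed=1)
        res = est.weighted_ols(X, y, np.full(len(y), 3.0))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), ols, atol=1e-10)

    def test_five_point_normal_equations(self):
        # solved by hand via (X'WX) b = X'Wy with X = [1, x]
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 4.0, 4.0])
        w = np.array([1.0, 1.0, 2.0, 1.0, 1.0])
        X = np.column_stack([np.ones(5), x])
        # X'WX = [[6, 12], [12, 34]]; X'Wy = [15, 38]; det = 60
        # b0 = (34*15 - 12*38)/60 = 54/60; b1 = (6*38 - 12*15)/60 = 48/60
        res = est.weighted_ols(X, y, w)
        np.testing.assert_allclose(res.params.to_numpy(),
                                   [54 / 60, 48 / 60], atol=1e-12)

    def test_collinear_column_dropped_and_logged(self):
        X, y, w, _ = design()
        X2 = np.column_stack([X, X[:, 1] * 2.0])
        res = est.weighted_ols(X2, y, w, names=["c", "a", "b", "a2"])
        assert res.dropped_collinear == ["a2"]

    def test_negative_weights_rejected(self):
        X, y, w, _ = design()
        w[0] = -1.0
        with pytest.raises(ValueError):
            est.weighted_ols(X, y, w)


class TestHC1:
    def test_zero_residuals_zero_se(self):
        X, _, w, beta = design()
        res = est.weighted_ols(X, X @ beta, w)
        assert (est.hc1_se(res) < 1e-8).all()

    def test_elementwise_sandwich_oracle(self):
        X, y, w, _ = design(n=25, seed=4)
        res = est.weighted_ols(X, y, w)
        n, k = X.shape
        bread = np.zeros((k, k))
        meat = np.zeros((k, k))
        for i in range(n):
            xi = X[i][:, None]
            bread += w[i] * xi @ xi.T
            meat += (w[i] * res.residuals[i]) ** 2 * (xi @ xi.T)
        binv = np.linalg.inv(bread)
        cov = binv @ meat @ binv * n / (n - k)
        np.testing.assert_allclose(
            est.hc1_se(res).to_numpy(), np.sqrt(np.diag(cov)), rtol=1e-10
        )

    def test_matches_statsmodels_wls_hc1(self):
        X, y, w, _ = design(n=80, seed=6, het=True)
        res = est.weighted_ols(X, y, w)
        sm_res = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
        np.testing.assert_allclose(est.hc1_se(res).to_numpy(), sm_res.bse,
                                   rtol=1e-8)

    def test_homoscedastic_hc1_close_to_classical(self):
        # one large homoscedastic fit: the sandwich and classical SEs agree
        X, y, w, _ = design(n=20_000, k=3, seed=7)
        w = np.ones(len(y))
        res = est.weighted_ols(X, y, w)
        n, k = X.shape
        s2 = res.residuals @ res.residuals / (n - k)
        classical = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        ratio = est.hc1_se(res).to_numpy() / classical
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_more_params_than_rows_rejected(self):
        X = np.eye(3)
        res = est.weighted_ols(X, np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            est.hc1_se(res)


class TestBreuschPagan:
    def test_type_one_error_rate(self):
        rejections = 0
        reps = 1000
        rng = np.random.default_rng(99)
        for _ in range(reps):
            n = 120
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = X @ np.array([1.0, 2.0]) + rng.normal(size=n)
            res = est.weighted_ols(X, y, np.ones(n))
            _, p = est.breusch_pagan(res)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.02  # ~3 binomial SDs

    def test_power_against_variance_proportional_to_covariate(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(50):
            n = 500
            x = rng.uniform(0.5, 2.0, size=n)
            X = np.column_stack([np.ones(n), x])
            y = X @ np.array([1.0, 2.0]) + rng.normal(size=n) * x
            res = est.weighted_ols(X, y, np.ones(n))
            _, p = est.breusch_pagan(res)
            hits += p < 0.05
        assert hits / 50 > 0.8

    def test_agrees_with_statsmodels_on_unweighted_fit(self):
        rng = np.random.default_rng(2)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=n) * np.exp(
            0.5 * X[:, 1]
        )
        res = est.weighted_ols(X, y, np.ones(n))
        lm, p = est.breusch_pagan(res)
        sm_lm, sm_p, _, _ = sm.stats.diagnostic.het_breuschpagan(
            res.residuals, X
        )
        assert lm == pytest.approx(sm_lm, rel=1e-8)
        assert p == pytest.approx(sm_p, rel=1e-8)

    def test_intercept_only_design_rejected(self):
        res = est.weighted_ols(np.ones((10, 1)), np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            est.breusch_pagan(res)

    def test_constant_residuals_degenerate(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        res = est.weighted_ols(X, X @ np.array([1.0, 2.0]), np.ones(10))
        lm, p = est.breusch_pagan(res)
        assert p == 1.0


class TestPercentEffect:
    def test_zero_effect(self):
        assert est.percent_effect(0.0, 10.0) == 0.0

    def test_ratio(self):
        assert est.percent_effect(-5.0, 10.0) == pytest.approx(-50.0)

    def test_near_zero_denominator_flagged(self):
        assert np.isnan(est.percent_effect(1.0, 1e-12))


class TestFDR:
    def test_single_p_unchanged(self):
        got = est.fdr_adjust(pd.Series([0.03]))
        assert got.iloc[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # step-up: min over j>=i of m*p_j/j = 0.04 for every rank
        got = est.fdr_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(got, [0.04] * 4)

    def test_monotone_in_rank_and_capped(self):
        rng = np.random.default_rng(8)
        p = pd.Series(rng.uniform(size=40))
        adj = est.fdr_adjust(p)
        order = np.argsort(p.to_numpy())
        assert (np.diff(adj.to_numpy()[order]) >= -1e-12).all()
        assert (adj <= 1).all()
        assert (adj >= p - 1e-12).all()

    def test_families_adjusted_separately(self):
        p = pd.Series([0.01, 0.04, 0.01, 0.04])
        fam = pd.Series(["a", "a", "b", "b"])
        got = est.fdr_adjust(p, fam)
        np.testing.assert_allclose(got, [0.02, 0.04, 0.02, 0.04])


class TestNullCalibration:
    def test_hc1_ci_coverage_under_null(self):
        """95% HC1 intervals for a null slope cover 0 at ~95% across
        heteroscedastic replicates."""
        rng = np.random.default_rng(123)
        reps, n = 500, 300
        cover = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            y = 1.0 + 0.0 * x + rng.normal(size=n) * np.exp(0.4 * x)
            res = est.weighted_ols(X, y, np.ones(n))
            se = est.hc1_se(res)
            lo = res.params.iloc[1] - 1.96 * se.iloc[1]
            hi = res.params.iloc[1] + 1.96 * se.iloc[1]
            cover += lo <= 0.0 <= hi
        assert 0.93 <= cover / reps <= 0.97
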