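"""STOCSY and the univariate layer: closed-form and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nmrmetab import (
    chi_square,
    geometric_mean_ci,
    logistic_adjusted,
    mann_whitney,
    spearman,
    stocsy,
    t_test,
)
from nmrmetab.oplsda import fit_opls_da
from nmrmetab.preprocess import apply_scaler, fit_scaler


class TestStocsy:
    def test_driver_column_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 20))
        ppm = np.linspace(9, 1, 20)
        res = stocsy(X, ppm, driver_ppm=ppm[7])
        assert res.driver_index == 7
        assert res.r[7] == pytest.approx(1.0)

    def test_anticorrelated_column(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 5))
        X[:, 3] = -X[:, 0]
        res = stocsy(X, np.linspace(5, 1, 5), driver_ppm=5.0)
        assert res.r[3] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson_and_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 50))
        ppm = np.linspace(9, 1, 50)
        res = stocsy(X, ppm, driver_ppm=ppm[17])
        for j in range(50):
            assert res.r[j] == pytest.approx(np.corrcoef(X[:, 17], X[:, j])[0, 1], abs=1e-12)
            assert res.cov[j] == pytest.approx(np.cov(X[:, 17], X[:, j])[0, 1], abs=1e-12)

    def test_zero_variance_driver_rejected(self):
        X = np.ones((5, 4))
        with pytest.raises(ValueError, match="zero variance"):
            stocsy(X, np.linspace(4, 1, 4), driver_ppm=4.0)

    def test_agrees_with_opls_loading_r_for_top_variable(self, preprocessed_effect):
        # with one predictive component and no orthogonal filtering both are
        # correlations against essentially the same latent direction
        m, y, _ = preprocessed_effect
        state = fit_scaler(m.intensities)
        model = fit_opls_da(apply_scaler(m.intensities, state), y, n_orth=0)
        top = state.kept_columns[int(np.argmax(np.abs(model.loading_r)))]
        res = stocsy(m.intensities, m.ppm, driver_ppm=m.ppm[top])
        kept_r = res.r[state.kept_columns]
        # STOCSY r is signed relative to the driver column, so the two
        # profiles agree up to the sign of the driver's own loading
        agreement = np.corrcoef(kept_r, model.loading_r)[0, 1]
        assert abs(agreement) > 0.9


def _exact_mw_oracle(a, b, u_obs):
    """Independent enumeration over all group assignments (handles ties)."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    lows = highs = total = 0
    for comb in itertools.combinations(range(n), na):
        ga = pooled[list(comb)]
        gb = pooled[[i for i in range(n) if i not in comb]]
        ranks = sps.rankdata(np.concatenate([ga, gb]))
        u = ranks[:na].sum() - na * (na + 1) / 2
        lows += u <= u_obs + 1e-9
        highs += u >= u_obs - 1e-9
        total += 1
    return lows / total, highs / total


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney([1, 2], [3, 4], tail="one")
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_groups_symmetric(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3], tail="two")
        assert res.statistic == pytest.approx(4.5)  # n_a n_b / 2
        assert res.p_value == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), seed=st.integers(0, 100))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=5)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(a + shift, b + shift)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_exact_path_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for na in (2, 3, 4):
            nb = 8 - na
            vals = rng.integers(0, 4, size=8).astype(float)  # forced ties
            a, b = vals[:na], vals[na:]
            res = mann_whitney(a, b, tail="one")
            p_low, p_high = _exact_mw_oracle(a, b, res.statistic)
            assert res.p_value == pytest.approx(min(p_low, p_high))

    def test_exact_and_normal_approximation_agree(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=5)
            exact = mann_whitney(a, b, tail="two", exact_max_n=10)
            approx = mann_whitney(a, b, tail="two", exact_max_n=0)
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_gives_unit_rho(self):
        assert spearman([1, 2, 3], [1, 4, 9]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3], [9, 4, 1]).statistic == pytest.approx(-1.0)

    def test_tied_data_equals_midrank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 2.0, 4.0, 4.0, 4.0, 8.0, 9.0])
        rho = spearman(x, y).statistic
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert res.n == (3,)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        log_res = t_test([1, 10, 100], [1, 10, 100], log_transform=True)
        assert log_res.statistic == pytest.approx(0.0)

    def test_pooled_toy_matches_closed_form(self):
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test(a, b, welch=False, tail="two")
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t_oracle = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=6)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_one_tailed_is_half_two_tailed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        assert t_test(a, b, tail="one").p_value == pytest.approx(
            t_test(a, b, tail="two").p_value / 2
        )

    def test_non_positive_with_log_rejected(self):
        with pytest.raises(ValueError, match="group b"):
            t_test([1.0, 2.0], [0.0, 2.0], log_transform=True)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_count_scaling_homogeneity(self):
        t1 = chi_square([[8, 2], [1, 9]]).statistic
        t3 = chi_square([[24, 6], [3, 27]]).statistic
        assert t3 == pytest.approx(3 * t1)

    def test_two_by_two_matches_hand_computation(self):
        table = np.array([[8.0, 2.0], [1.0, 9.0]])
        chi_oracle = 0.0
        rs, cs, n = table.sum(1), table.sum(0), table.sum()
        for i in range(2):
            for j in range(2):
                e = rs[i] * cs[j] / n
                chi_oracle += (table[i, j] - e) ** 2 / e
        assert chi_square(table).statistic == pytest.approx(chi_oracle, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square([[0, 0], [3, 4]])


class TestGeometricMeanCi:
    def test_closed_form(self):
        gm, lo, hi = geometric_mean_ci([1.0, 100.0])
        assert gm == pytest.approx(10.0)
        assert lo < gm < hi

    def test_degenerate_equal_values(self):
        gm, lo, hi = geometric_mean_ci([7.0, 7.0, 7.0])
        assert gm == lo == hi == pytest.approx(7.0)

    def test_matches_independent_log_scale_interval(self):
        x = np.array([12.0, 30.0, 45.0, 80.0, 150.0])
        gm, lo, hi = geometric_mean_ci(x, level=0.95)
        logs = np.log(x)
        half = sps.t.ppf(0.975, 4) * logs.std(ddof=1) / np.sqrt(5)
        assert gm == pytest.approx(np.exp(logs.mean()), abs=1e-12)
        assert lo == pytest.approx(np.exp(logs.mean() - half), abs=1e-12)
        assert hi == pytest.approx(np.exp(logs.mean() + half), abs=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            geometric_mean_ci([1.0, 0.0, 3.0])


def _newton_logistic(X, y, iters=200):
    """Independent Newton-Raphson oracle for logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        H = X.T @ (W[:, None] * X)
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


class TestLogisticAdjusted:
    def _toy(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        met = rng.normal(size=n)
        cov = rng.integers(0, 2, n).astype(float)
        eta = 0.8 * met - 0.5 * cov + 0.2
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        if y.sum() in (0, n):  # both classes required
            y[0], y[-1] = 1.0, 0.0
        return y, met, cov

    def test_matches_newton_oracle(self):
        y, met, cov = self._toy(seed=11)
        res = logistic_adjusted(y, met, cov)
        assert not res.separation
        X = np.column_stack([np.ones_like(met), met, cov])
        oracle = _newton_logistic(X, y)
        np.testing.assert_allclose(res.params, oracle, atol=1e-6)
        assert res.p_values.shape == (3,)

    def test_separation_flagged_not_returned_silently(self):
        y = np.repeat([1.0, 0.0], 10)
        res = logistic_adjusted(y, np.random.default_rng(0).normal(size=20), y)
        assert res.separation
        assert res.p_values is None

    def test_null_metabolite_coefficient_small(self):
        betas, sig = [], 0
        for s in range(12):
            rng = np.random.default_rng(400 + s)
            y = rng.permutation(np.repeat([1.0, 0.0], 40))
            met = rng.normal(size=80)
            cov = rng.integers(0, 2, 80).astype(float)
            res = logistic_adjusted(y, met, cov)
            if not res.separation:
                betas.append(abs(res.params[1]))
                sig += res.p_values[1] < 0.05
        assert np.median(betas) < 0.5
        assert sig <= 3

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="10"):
            logistic_adjusted([1, 0, 1], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0])


class TestOrderInvariance:
    def test_tests_invariant_to_sample_order(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(size=7), rng.normal(size=9)
        perm_a, perm_b = rng.permutation(a), rng.permutation(b)
        assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(perm_a, perm_b).p_value)
        assert t_test(a, b).p_value == pytest.approx(t_test(perm_a, perm_b).p_value)
        x, y = rng.normal(size=10), rng.normal(size=10)
        order = rng.permutation(10)
        assert spearman(x, y).statistic == pytest.approx(spearman(x[order], y[order]).statistic)
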