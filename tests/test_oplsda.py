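"""PLS-DA / O-PLS-DA: closed-form oracles, orthogonality, prediction."""

import numpy as np
import pytest

from nmrmetab import backscaled_loadings, fit_opls_da, fit_pls_da, predict
from nmrmetab.oplsda import ClassVector, make_class_vector
from nmrmetab.preprocess import apply_scaler, fit_scaler


def _toy(n=12, p=8, seed=0, effect=2.0):
    """Centred matrix with one informative direction."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, 0.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    X -= X.mean(axis=0)
    return X, y


class TestPlsDa:
    def test_perfect_column_gives_r2y_one(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1.0, 0.0], 6)
        X = rng.normal(size=(12, 5)) * 1e-9
        X[:, 2] = y - y.mean()
        X -= X.mean(axis=0)
        model = fit_pls_da(X, y, 1)
        assert model.r2y > 1 - 1e-8

    def test_one_component_closed_form_oracle(self):
        # oracle: direct matrix arithmetic for single-component PLS1
        X, y = _toy(n=5 + 5, p=3, seed=3)
        yc = y - y.mean()
        w = X.T @ yc
        w = w / np.linalg.norm(w)
        t = X @ w
        c = (yc @ t) / (t @ t)
        p = (X.T @ t) / (t @ t)
        model = fit_pls_da(X, y, 1)
        np.testing.assert_allclose(model.W[:, 0], w, atol=1e-12)
        np.testing.assert_allclose(model.T[:, 0], t, atol=1e-12)
        np.testing.assert_allclose(model.P[:, 0], p, atol=1e-12)
        np.testing.assert_allclose(model.c[0], c, atol=1e-12)

    def test_class_flip_symmetry(self):
        X, y = _toy(seed=5)
        m1 = fit_pls_da(X, y, 2)
        m2 = fit_pls_da(X, 1.0 - y, 2)
        np.testing.assert_allclose(m2.T, -m1.T, atol=1e-10)
        np.testing.assert_allclose(m2.W, -m1.W, atol=1e-10)
        # c = y't/t't is invariant: both y and t flip
        np.testing.assert_allclose(m2.c, m1.c, atol=1e-10)
        # fitted y-hat respects the flipped coding
        yhat1 = m1.T @ m1.c + m1.y_mean
        yhat2 = m2.T @ m2.c + m2.y_mean
        np.testing.assert_allclose(yhat2, 1.0 - yhat1, atol=1e-10)

    def test_r2y_monotone_in_components(self):
        X, y = _toy(n=20, p=15, seed=7)
        model = fit_pls_da(X, y, 6)
        assert np.all(np.diff(model.r2y_cum) >= -1e-12)
        assert np.all((model.r2y_cum >= -1e-12) & (model.r2y_cum <= 1 + 1e-12))

    def test_single_class_and_rank_errors(self):
        X, y = _toy()
        with pytest.raises(ValueError, match="both classes"):
            fit_pls_da(X, np.ones_like(y), 1)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls_da(X, y, 50)


class TestOplsDa:
    def test_zero_orth_equals_one_component_pls(self):
        X, y = _toy(n=16, p=10, seed=11)
        pls = fit_pls_da(X, y, 1)
        opls = fit_opls_da(X, y, n_orth=0)
        np.testing.assert_allclose(opls.w, pls.W[:, 0], atol=1e-10)
        np.testing.assert_allclose(opls.t, pls.T[:, 0], atol=1e-10)
        np.testing.assert_allclose(opls.p, pls.P[:, 0], atol=1e-10)
        assert abs(opls.c - pls.c[0]) < 1e-10
        assert abs(opls.r2y - pls.r2y) < 1e-10

    def test_orthogonal_scores_orthogonal_to_y(self):
        X, y = _toy(n=20, p=30, seed=13)
        model = fit_opls_da(X, y, n_orth=3)
        yc = y - y.mean()
        for k in range(3):
            t_o = model.T_orth[:, k]
            cosine = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert cosine < 1e-8
            # also orthogonal to the predictive score
            cos_t = abs(t_o @ model.t) / (np.linalg.norm(t_o) * np.linalg.norm(model.t))
            assert cos_t < 1e-8

    def test_manual_deflation_oracle(self):
        # one structured y-orthogonal confounder; removing it by explicit
        # deflation must reproduce the O-PLS predictive component
        X, y = _toy(n=20, p=12, seed=17)
        model = fit_opls_da(X, y, n_orth=1)
        X_defl = X - np.outer(model.T_orth[:, 0], model.P_orth[:, 0])
        pls = fit_pls_da(X_defl, y, 1)
        np.testing.assert_allclose(model.t, pls.T[:, 0], atol=1e-10)
        np.testing.assert_allclose(model.w, pls.W[:, 0], atol=1e-10)

    def test_predictive_scores_invariant_to_added_orthogonal_structure(self):
        # adding structured variance along an orthogonal weight direction
        # (scores x weights) is absorbed by the same orthogonal round and
        # leaves the predictive component unchanged
        X, y = _toy(n=20, p=40, seed=3)
        base = fit_opls_da(X, y, n_orth=1)
        for amp in (2.0, 10.0):
            X2 = X + amp * np.outer(base.T_orth[:, 0], base.W_orth[:, 0])
            model = fit_opls_da(X2, y, n_orth=1)
            rel = np.max(np.abs(model.t - base.t)) / np.linalg.norm(base.t)
            assert rel < 1e-8

    def test_predictive_score_positively_correlated_with_y(self):
        X, y = _toy(seed=19)
        model = fit_opls_da(X, y, n_orth=1)
        assert np.corrcoef(model.t, y)[0, 1] > 0

    def test_r2_bounds(self):
        X, y = _toy(n=14, p=40, seed=23)
        model = fit_opls_da(X, y, n_orth=2)
        assert 0 <= model.r2x <= 1
        assert 0 <= model.r2y <= 1


class TestPredict:
    def test_training_scores_reproduced(self):
        X, y = _toy(n=18, p=25, seed=29)
        model = fit_opls_da(X, y, n_orth=2)
        t_new, t_orth_new, y_hat = predict(model, X)
        np.testing.assert_allclose(t_new, model.t, atol=1e-10)
        np.testing.assert_allclose(t_orth_new, model.T_orth, atol=1e-10)

    def test_zero_matrix_predicts_class_mean(self):
        X, y = _toy(seed=31)
        model = fit_opls_da(X, y, n_orth=1)
        _, _, y_hat = predict(model, np.zeros((3, X.shape[1])))
        np.testing.assert_allclose(y_hat, model.y_mean, atol=1e-12)

    def test_column_mismatch_rejected(self):
        X, y = _toy(seed=37)
        model = fit_opls_da(X, y, n_orth=0)
        with pytest.raises(ValueError, match="columns"):
            predict(model, np.zeros((2, X.shape[1] + 1)))

    def test_held_out_prediction_matches_hand_rolled_oracle(self):
        # 6-sample toy: fit on 4, predict 2, against an independent oracle
        rng = np.random.default_rng(41)
        X = rng.normal(size=(6, 4))
        y = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        train, test = slice(0, 4), slice(4, 6)
        Xt, yt = X[train] - X[train].mean(axis=0), y[train]
        model = fit_opls_da(Xt, yt, n_orth=1)
        Xn = X[test] - X[train].mean(axis=0)
        _, _, y_hat = predict(model, Xn)

        # oracle: independent numpy re-derivation of OSC + PLS1 prediction
        yc = yt - yt.mean()
        w = Xt.T @ yc / np.linalg.norm(Xt.T @ yc)
        t = Xt @ w
        p = Xt.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        w_o = w_o / np.linalg.norm(w_o)
        t_o = Xt @ w_o
        p_o = Xt.T @ t_o / (t_o @ t_o)
        Xd = Xt - np.outer(t_o, p_o)
        w2 = Xd.T @ yc / np.linalg.norm(Xd.T @ yc)
        t2 = Xd @ w2
        c2 = yc @ t2 / (t2 @ t2)
        Xn_d = Xn - np.outer(Xn @ w_o, p_o)
        oracle = (Xn_d @ w2) * c2 + yt.mean()
        np.testing.assert_allclose(y_hat, oracle, atol=1e-10)


class TestBackscaledLoadings:
    def test_r_matches_brute_force_pearson(self, preprocessed_effect):
        m, y, _ = preprocessed_effect
        state = fit_scaler(m.intensities)
        Xs = apply_scaler(m.intensities, state)
        model = fit_opls_da(Xs, y, n_orth=1, scaling_state=state)
        profile = backscaled_loadings(model, state, ppm=m.ppm[state.kept_columns])
        brute = np.array([np.corrcoef(model.t, Xs[:, j])[0, 1] for j in range(Xs.shape[1])])
        np.testing.assert_allclose(profile.r, brute, atol=1e-12)
        assert np.all(profile.abs_r <= 1 + 1e-12)
        np.testing.assert_allclose(profile.backscaled, model.p * state.kept_sds, atol=1e-14)

    def test_perfect_column_has_near_unit_correlation(self):
        # the floor below 1 comes from the unit-variance-scaled noise
        # columns leaking into the score, shrinking with n
        rng = np.random.default_rng(43)
        y = np.repeat([1.0, 0.0], 20)
        X = rng.normal(size=(40, 4)) * 1e-6
        X[:, 1] = y
        state = fit_scaler(X)
        Xs = apply_scaler(X, state)
        model = fit_opls_da(Xs, y, n_orth=0, scaling_state=state)
        profile = backscaled_loadings(model)
        assert abs(profile.r[1]) > 0.98

    def test_dropped_column_absent_from_profile(self):
        X = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 1.0], [3.0, 5.0, 3.0], [0.0, 5.0, 2.5]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        state = fit_scaler(X)
        model = fit_opls_da(apply_scaler(X, state), y, n_orth=0, scaling_state=state)
        profile = backscaled_loadings(model, state)
        assert profile.backscaled.size == 2  # constant column 1 dropped

    def test_missing_scaling_state_rejected(self):
        X, y = _toy(seed=47)
        model = fit_opls_da(X, y, n_orth=0)
        with pytest.raises(ValueError, match="ScalingState"):
            backscaled_loadings(model)


class TestClassVector:
    def test_make_class_vector_coding(self):
        labels = np.array(["case", "control", "case", "other", "control"])
        mask, cv = make_class_vector(labels, "case", "control")
        np.testing.assert_array_equal(mask, [True, True, True, False, True])
        np.testing.assert_array_equal(cv.y, [1.0, 0.0, 1.0, 0.0])
        assert cv.class_names == {0: "control", 1: "case"}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ClassVector(np.ones(4), {0: "a", 1: "b"})
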