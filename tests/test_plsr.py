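"""NIPALS PLS1 core: oracle equivalence, CV, one-sigma selection, loadings."""

import numpy as np
import pytest

from glucospec import (
    CVResult,
    fit_plsr,
    get_loadings,
    load_model,
    loo_cv,
    predict,
    save_model,
    select_ncomp_one_sigma,
)
from glucospec.exceptions import DegenerateInputError


def ols_predictions(X, y, Xnew):
    """Independent least-squares oracle via the normal equations/pseudoinverse."""
    Xc = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.pinv(Xc) @ y
    return np.column_stack([np.ones(len(Xnew)), Xnew]) @ beta


def brute_force_loo(X, y, max_ncomp, scale=True):
    """Explicit refit-per-left-out-sample LOO oracle, one fit per (fold, ncomp)."""
    n = len(y)
    residuals = np.zeros((n, max_ncomp + 1))
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(max_ncomp + 1):
            model = fit_plsr(X[keep], y[keep], ncomp=a, scale=scale)
            residuals[i, a] = y[i] - predict(model, X[i : i + 1])[0]
    return np.sqrt((residuals**2).mean(axis=0))


class TestFit:
    def test_single_informative_column_exact_fit(self):
        rng = np.random.default_rng(0)
        X = np.zeros((12, 6))
        X[:, 3] = rng.normal(size=12)
        y = 2.0 * X[:, 3]
        model = fit_plsr(X, y, ncomp=1, scale=False)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-10)

    def test_full_rank_equals_least_squares(self):
        # oracle equivalence over 100 random instances
        rng = np.random.default_rng(123)
        for _ in range(100):
            X = rng.normal(size=(10, 5))
            y = rng.normal(size=10)
            model = fit_plsr(X, y, ncomp=5, scale=False)
            np.testing.assert_allclose(
                predict(model, X), ols_predictions(X, y, X), atol=1e-8
            )

    def test_matches_sklearn_pls_predictions(self):
        # independent implementation cross-check at several component counts
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(99)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + 0.3 * rng.normal(size=30)
        for ncomp in (1, 3, 6):
            model = fit_plsr(X, y, ncomp=ncomp, scale=True)
            sk = PLSRegression(n_components=ncomp, scale=True).fit(X, y[:, None])
            np.testing.assert_allclose(
                predict(model, X), sk.predict(X).ravel(), atol=1e-10
            )

    def test_zero_components_predicts_mean(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(8, 4)), rng.normal(size=8)
        model = fit_plsr(X, y, ncomp=0)
        np.testing.assert_allclose(predict(model, X), y.mean())

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(20, 10)), rng.normal(size=20)
        T = fit_plsr(X, y, ncomp=6).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10

    def test_rmsec_non_increasing_in_ncomp(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=25)
        errors = []
        for a in range(0, 9):
            model = fit_plsr(X, y, ncomp=a)
            errors.append(np.sqrt(np.mean((y - predict(model, X)) ** 2)))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_column_scaling_invariance_with_scale_on(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 7))
        y = X @ rng.normal(size=7)
        Xs = X.copy()
        Xs[:, 2] *= 37.5
        m1, m2 = fit_plsr(X, y, 3, scale=True), fit_plsr(Xs, y, 3, scale=True)
        np.testing.assert_allclose(predict(m1, X), predict(m2, Xs), atol=1e-8)

    def test_prediction_at_center_is_y_mean(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(15, 7)), rng.normal(size=15)
        model = fit_plsr(X, y, 3)
        assert predict(model, model.x_center[None, :])[0] == pytest.approx(y.mean())

    def test_coef_consistent_with_decomposition(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(18, 9)), rng.normal(size=18)
        model = fit_plsr(X, y, 4)
        # reconstruct predictions from W, P, q instead of (coef, intercept)
        Xc = (X - model.x_center) / model.x_scale
        R = model.x_loadings.T @ model.weights
        alpha = np.linalg.solve(R, model.y_loadings)
        yhat = model.y_center + model.y_scale * (Xc @ (model.weights @ alpha))
        np.testing.assert_allclose(yhat, predict(model, X), atol=1e-9)

    def test_invalid_ncomp_rejected(self):
        X, y = np.eye(5), np.arange(5.0)
        with pytest.raises(ValueError):
            fit_plsr(X, y, ncomp=7)

    def test_zero_variance_column_with_scale_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 4))
        X[:, 1] = 3.0
        with pytest.raises(DegenerateInputError):
            fit_plsr(X, rng.normal(size=10), 2, scale=True)

    def test_empty_prediction_input(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        model = fit_plsr(X, y, 2)
        assert predict(model, np.empty((0, 4))).shape == (0,)

    def test_column_count_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        model = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="columns"):
            predict(model, np.zeros((3, 5)))


class TestLooCV:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        for scale in (True, False):
            cv = loo_cv(X, y, max_ncomp=3, scale=scale)
            oracle = brute_force_loo(X, y, max_ncomp=3, scale=scale)
            np.testing.assert_allclose(cv.rmsecv, oracle, atol=1e-9)

    def test_noiseless_linear_response_reaches_zero_error(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        cv = loo_cv(X, y, max_ncomp=4)
        assert cv.rmsecv[4] < 1e-8 * np.abs(y).max()

    def test_pure_noise_overfits_at_high_ncomp(self):
        # null model should beat large models when y is independent of X
        rng = np.random.default_rng(12)
        wins = 0
        for _ in range(20):
            X = rng.normal(size=(15, 10))
            y = rng.normal(size=15)
            cv = loo_cv(X, y, max_ncomp=8)
            wins += cv.rmsecv[0] <= cv.rmsecv[8]
        assert wins >= 15

    def test_chosen_ncomp_never_exceeds_argmin(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12) + 0.5 * rng.normal(size=25)
        cv = loo_cv(X, y, max_ncomp=8)
        assert cv.chosen_ncomp <= int(np.argmin(cv.rmsecv))

    def test_max_ncomp_bounds_enforced(self):
        rng = np.random.default_rng(14)
        X, y = rng.normal(size=(6, 10)), rng.normal(size=6)
        with pytest.raises(ValueError):
            loo_cv(X, y, max_ncomp=5)  # > n - 2


class TestOneSigmaSelection:
    def test_strictly_decreasing_with_zero_se_selects_argmin(self):
        cv = CVResult(np.array([5.0, 4.0, 3.0, 2.0]), np.zeros(4), 0)
        assert select_ncomp_one_sigma(cv) == 3

    def test_hand_worked_case(self):
        cv = CVResult(np.array([5.0, 3.0, 2.9, 2.88]),
                      np.array([0.0, 0.0, 0.0, 0.15]), 0)
        assert select_ncomp_one_sigma(cv) == 1  # 3.0 <= 2.88 + 0.15

    def test_flat_curve_selects_null_model(self):
        cv = CVResult(np.full(5, 2.0), np.full(5, 0.1), 0)
        assert select_ncomp_one_sigma(cv) == 0


class TestLoadings:
    def test_informative_column_dominates_first_loading(self):
        rng = np.random.default_rng(15)
        X = 0.01 * rng.normal(size=(20, 6))
        X[:, 4] += rng.normal(size=20)
        y = 3.0 * X[:, 4]
        model = fit_plsr(X, y, 1, scale=False)
        loading = get_loadings(model, 1)
        assert loading.shape == (6,)
        assert np.argmax(np.abs(loading)) == 4

    def test_loadings_invariant_to_response_rescaling(self):
        # fresh- vs dry-weight responses proportional by a constant give the
        # same loading structure on identical spectra
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=30)
        m_fresh = fit_plsr(X, y, 3, scale=True)
        m_dry = fit_plsr(X, y / (100 * 0.122), 3, scale=True)
        for a in (1, 2, 3):
            np.testing.assert_allclose(
                get_loadings(m_fresh, a), get_loadings(m_dry, a), atol=1e-9
            )

    def test_component_out_of_range(self):
        rng = np.random.default_rng(17)
        model = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ValueError):
            get_loadings(model, 3)


class TestSerialization:
    def test_round_trip_predictions_bit_exact(self, tmp_path):
        rng = np.random.default_rng(18)
        X, y = rng.normal(size=(20, 10)), rng.normal(size=20)
        model = fit_plsr(X, y, 4)
        path = save_model(model, tmp_path / "model.txt",
                          wavelengths=np.arange(950, 1000, 5, dtype=float),
                          preprocess="snv|detrend:2")
        loaded, wavelengths, preprocess = load_model(path)
        np.testing.assert_array_equal(predict(loaded, X), predict(model, X))
        assert preprocess == "snv|detrend:2"
        assert wavelengths[0] == 950.0 and len(wavelengths) == 10
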