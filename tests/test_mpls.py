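import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from podnirs import cross_validate, fit_mpls


def _random_problem(seed, n=60, p=200, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * 0.1
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestPLS1Limit:
    """With residual scaling off, the fit must be exactly NIPALS PLS1."""

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("a", [1, 4, 8])
    def test_unscaled_predictions_match_independent_pls1(self, seed, a):
        X, y = _random_problem(seed)
        model = fit_mpls(X, y, a, scale_residuals=False)
        oracle = PLSRegression(n_components=a, scale=False).fit(X, y)
        np.testing.assert_allclose(model.predict(X),
                                   oracle.predict(X).ravel(), atol=1e-8)

    def test_unscaled_out_of_sample_predictions_match(self):
        X, y = _random_problem(7)
        Xnew = np.random.default_rng(8).standard_normal((10, X.shape[1]))
        model = fit_mpls(X, y, 5, scale_residuals=False)
        oracle = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(model.predict(Xnew),
                                   oracle.predict(Xnew).ravel(), atol=1e-8)


class TestFit:
    def test_exact_rank_recovery_noiseless(self):
        rng = np.random.default_rng(1)
        T = rng.standard_normal((40, 3))
        X = T @ rng.standard_normal((3, 80))
        y = T @ np.array([1.0, -2.0, 0.5])
        model = fit_mpls(X, y, 3)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_first_factor_direction_is_covariance(self):
        X, y = _random_problem(3)
        model = fit_mpls(X, y, 1)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        cos = abs(model.weights[0] @ w)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_training_sec_non_increasing_in_factors(self):
        X, y = _random_problem(4)
        model = fit_mpls(X, y, 10)
        preds = model.predict_by_factor(X)
        sse = [np.sum((y - preds[a]) ** 2) for a in range(10)]
        assert np.all(np.diff(sse) <= 1e-8)

    def test_prediction_invariant_to_global_absorbance_offset(self):
        X, y = _random_problem(5)
        m1 = fit_mpls(X, y, 4)
        m2 = fit_mpls(X + 7.5, y, 4)
        np.testing.assert_allclose(m1.predict(X + 123.0),
                                   m2.predict(X + 123.0 + 7.5), atol=1e-7)

    def test_center_spectrum_predicts_center_y(self):
        X, y = _random_problem(6)
        model = fit_mpls(X, y, 3)
        assert model.predict(model.x_center[None])[0] == pytest.approx(
            model.y_center, abs=1e-9)

    def test_duplicated_rows_get_duplicated_predictions(self):
        X, y = _random_problem(9)
        model = fit_mpls(X, y, 3)
        p = model.predict(np.vstack([X[0], X[0]]))
        assert p[0] == p[1]

    def test_scaled_fit_differs_from_unscaled(self):
        X, y = _random_problem(10)
        scaled = fit_mpls(X, y, 5, scale_residuals=True)
        unscaled = fit_mpls(X, y, 5, scale_residuals=False)
        assert not np.allclose(scaled.predict(X), unscaled.predict(X))

    def test_y_scaling_variant_still_predicts(self):
        X, y = _random_problem(11)
        model = fit_mpls(X, y, 4, scale_residuals=True, scale_y=True)
        assert np.sum((y - model.predict(X)) ** 2) < np.sum((y - y.mean()) ** 2)

    def test_degenerate_inputs_rejected(self):
        X, y = _random_problem(12, n=20)
        with pytest.raises(ValueError):
            fit_mpls(X, np.ones(20), 2)       # zero-variance y
        with pytest.raises(ValueError):
            fit_mpls(X, y, 20)                # n_factors >= n
        with pytest.raises(ValueError):
            fit_mpls(X, y, 0)

    def test_serialization_round_trip(self, tmp_path):
        X, y = _random_problem(13)
        model = fit_mpls(X, y, 4)
        path = tmp_path / "model.json"
        model.to_json(path)
        from podnirs import MPLSModel

        back = MPLSModel.from_json(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X),
                                   atol=1e-12)


class TestCrossValidate:
    def test_fold_sizes_balanced_114_over_6(self):
        X, y = _random_problem(20, n=114, p=60)
        cv = cross_validate(X, y, max_factors=4, passes=0)
        counts = np.bincount(cv.fold_assignment)
        assert counts.size == 6
        assert np.all(counts == 19)

    def test_noiseless_low_rank_selects_few_factors(self):
        rng = np.random.default_rng(21)
        T = rng.standard_normal((60, 3))
        X = T @ rng.standard_normal((3, 80))
        y = T @ np.array([2.0, 1.0, -1.0])
        cv = cross_validate(X, y, max_factors=10)
        assert cv.optimal_factors <= 4
        assert cv.secv < 1e-6 * y.std(ddof=1)

    def test_null_signal_rpd_near_one(self):
        X, _ = _random_problem(22, n=72, p=60)
        rpds = []
        for s in range(5):
            y = np.random.default_rng(1000 + s).standard_normal(72)
            rpds.append(cross_validate(X, y, max_factors=8).rpd_cv)
        assert abs(np.mean(rpds) - 1.0) < 0.15

    def test_planted_chemistry_outlier_removed_by_t_pass(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((60, 40))
        beta = rng.standard_normal(40) * 0.3
        y = X @ beta + 0.05 * rng.standard_normal(60)
        y[13] += 10 * y.std()
        cv = cross_validate(X, y, max_factors=6)
        removed = {i for p in cv.t_removed for i in p}
        assert 13 in removed
        assert 13 not in cv.surviving_idx

    def test_at_most_two_elimination_passes(self):
        X, y = _random_problem(24, n=80, p=50, noise=2.0)
        cv = cross_validate(X, y, max_factors=6, passes=2)
        assert cv.n_passes <= 2

    def test_too_few_samples_rejected(self):
        X, y = _random_problem(25, n=10, p=20)
        with pytest.raises(ValueError):
            cross_validate(X, y, max_factors=2, n_segments=6)
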