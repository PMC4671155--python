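"""Calibration engines: MLR wavelength selection, PCR, NIPALS PLS1, LOO selection."""

import numpy as np
import pytest

import hayspec as hs
from hayspec.regression import best_mlr_pair, _loo_predictions_all_k


def ols_predictions(X, y, X_new):
    """Minimum-norm least squares with intercept (pseudoinverse oracle)."""
    Xc = X - X.mean(axis=0)
    coef = np.linalg.pinv(Xc) @ (y - y.mean())
    return y.mean() + (X_new - X.mean(axis=0)) @ coef


class TestCorrelationSpectrum:
    def test_self_correlation(self, rng):
        X = rng.standard_normal((20, 6))
        r = hs.correlation_spectrum(X, X[:, 3])
        assert r[3] == pytest.approx(1.0)

    def test_constant_column_convention(self, rng):
        X = rng.standard_normal((15, 4))
        X[:, 2] = 5.0
        r = hs.correlation_spectrum(X, rng.standard_normal(15))
        assert r[2] == 0.0

    def test_antisymmetry(self, rng):
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        assert np.allclose(hs.correlation_spectrum(X, -y),
                           -hs.correlation_spectrum(X, y))


class TestSelectMlrWavelengths:
    def test_planted_column_found_first(self, rng):
        X = rng.standard_normal((40, 12))
        y = X[:, 7] + 1e-6 * rng.standard_normal(40)
        assert hs.select_mlr_wavelengths(X, y, 1) == [7]

    def test_greedy_matches_exhaustive_pair_search(self, rng):
        """On a synthetic 30x20 problem, greedy selection equals brute force."""
        X = rng.standard_normal((30, 20))
        y = 2 * X[:, 4] - X[:, 11] + 0.05 * rng.standard_normal(30)
        greedy = set(hs.select_mlr_wavelengths(X, y, 2))
        assert greedy == set(best_mlr_pair(X, y))

    def test_singleton_reduction(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        j = hs.select_mlr_wavelengths(X, y, 1)[0]
        assert j == int(np.argmax(np.abs(hs.correlation_spectrum(X, y))))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            hs.select_mlr_wavelengths(rng.standard_normal((3, 5)),
                                      rng.standard_normal(3), 2)


class TestFitMlr:
    def test_exact_recovery(self, rng):
        X = rng.standard_normal((30, 10))
        y = 2.0 * X[:, 2] - X[:, 5] + 1.0
        model = hs.fit_mlr(X, y, [2, 5])
        assert model.coef[2] == pytest.approx(2.0, abs=1e-10)
        assert model.coef[5] == pytest.approx(-1.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_selection_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="duplicate"):
            hs.fit_mlr(X, rng.standard_normal(20), [1, 1])

    def test_collinear_columns_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 3] = 2 * X[:, 1]
        with pytest.raises(ValueError, match="collinear"):
            hs.fit_mlr(X, rng.standard_normal(20), [1, 3])

    def test_residuals_orthogonal_to_design(self, rng):
        """Normal equations: residuals must be orthogonal to the fitted columns."""
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        model = hs.fit_mlr(X, y, [0, 4, 6])
        resid = y - hs.predict(model, X)
        for j in (0, 4, 6):
            assert abs(resid @ X[:, j]) < 1e-8
        assert abs(resid.sum()) < 1e-8


class TestFitPcr:
    def test_full_rank_matches_least_squares(self, rng):
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        model = hs.fit_pcr(X, y, 8)
        assert np.allclose(hs.predict(model, X), ols_predictions(X, y, X), atol=1e-8)

    def test_rank1_exact_subspace(self, rng):
        t = rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(6))
        y = 3.0 * t
        model = hs.fit_pcr(X, y, 1)
        assert np.allclose(hs.predict(model, X), y, atol=1e-8)

    def test_coefficients_in_loading_span(self, rng):
        X = rng.standard_normal((30, 12))
        y = rng.standard_normal(30)
        k = 4
        model = hs.fit_pcr(X, y, k)
        vt = model.metadata["loadings"]
        # projecting the coefficient vector onto the k loadings reproduces it
        proj = vt.T @ (vt @ model.coef)
        assert np.allclose(proj, model.coef, atol=1e-10)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            hs.fit_pcr(rng.standard_normal((10, 5)), rng.standard_normal(10), 10)


class TestFitPls:
    def test_full_rank_matches_least_squares(self, rng):
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        model = hs.fit_pls(X, y, 8)
        assert np.allclose(hs.predict(model, X), ols_predictions(X, y, X), atol=1e-8)

    def test_rank1_single_component_perfect(self, rng):
        t = rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(6))
        y = 2.0 * t + 1.0
        model = hs.fit_pls(X, y, 1)
        assert np.allclose(hs.predict(model, X), y, atol=1e-8)

    def test_score_orthogonality(self, rng):
        X = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        model = hs.fit_pls(X, y, 8)
        T = model.metadata["scores"]
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            hs.fit_pls(rng.standard_normal((10, 5)), np.full(10, 2.0), 2)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against scikit-learn's PLS regression."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((30, 15))
        y = rng.standard_normal(30)
        ours = hs.fit_pls(X, y, 5)
        ref = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y)
        assert np.allclose(hs.predict(ours, X), ref.predict(X).ravel(), atol=1e-8)


class TestMethodRelations:
    def test_triple_equivalence_at_full_rank(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        p_pls = hs.predict(hs.fit_pls(X, y, 6), X)
        p_pcr = hs.predict(hs.fit_pcr(X, y, 6), X)
        assert np.allclose(p_pls, p_pcr, atol=1e-8)
        assert np.allclose(p_pls, ols_predictions(X, y, X), atol=1e-8)

    def test_pls_calibration_rmse_monotone_in_k(self, rng):
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        rmses = [hs.rmse(y, hs.predict(hs.fit_pls(X, y, k), X))
                 for k in range(1, 10)]
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_pls_beats_pcr_in_calibration(self, rng):
        """At equal k, PLS (covariance-directed) fits y at least as well."""
        for _ in range(10):
            X = rng.standard_normal((30, 25))
            y = rng.standard_normal(30)
            for k in (1, 3, 5):
                e_pls = hs.rmse(y, hs.predict(hs.fit_pls(X, y, k), X))
                e_pcr = hs.rmse(y, hs.predict(hs.fit_pcr(X, y, k), X))
                assert e_pls <= e_pcr + 1e-10

    def test_sample_order_invariance(self, rng):
        X = rng.standard_normal((30, 12))
        y = rng.standard_normal(30)
        perm = rng.permutation(30)
        for fit, k in ((hs.fit_pls, 4), (hs.fit_pcr, 4)):
            a = fit(X, y, k)
            b = fit(X[perm], y[perm], k)
            assert np.allclose(a.coef, b.coef, atol=1e-8)
        m1 = hs.fit_mlr(X, y, [1, 5])
        m2 = hs.fit_mlr(X[perm], y[perm], [1, 5])
        assert np.allclose(m1.coef, m2.coef, atol=1e-8)


class TestPredict:
    def test_consistency_on_calibration_set(self, rng):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        model = hs.fit_pls(X, y, 3)
        assert np.allclose(hs.predict(model, X), hs.predict(model, X.copy()))

    def test_serialization_roundtrip(self, rng, tmp_path):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        for model in (hs.fit_pls(X, y, 3), hs.fit_pcr(X, y, 3),
                      hs.fit_mlr(X, y, [0, 2])):
            model.metadata = {}
            path = tmp_path / f"{model.method}.json"
            model.to_json(path)
            reloaded = hs.CalibrationModel.from_json(path)
            assert np.array_equal(hs.predict(model, X), hs.predict(reloaded, X))

    def test_linearity_in_inputs(self, rng):
        X = rng.standard_normal((20, 8))
        model = hs.fit_pls(X, rng.standard_normal(20), 3)
        x = X[0].copy()
        base = hs.predict(model, x[None, :])[0]
        delta = 0.37
        x[5] += delta
        shifted = hs.predict(model, x[None, :])[0]
        assert shifted - base == pytest.approx(model.coef[5] * delta, rel=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        model = hs.fit_pls(rng.standard_normal((20, 8)),
                           rng.standard_normal(20), 2)
        with pytest.raises(ValueError, match="columns"):
            hs.predict(model, rng.standard_normal((5, 7)))


class TestSelectNComponents:
    def test_planted_three_factor_recovery(self, rng):
        T = rng.standard_normal((60, 3))
        P = rng.standard_normal((3, 30))
        X = T @ P + 1e-6 * rng.standard_normal((60, 30))
        y = T @ np.array([1.0, -2.0, 0.5]) + 1e-6 * rng.standard_normal(60)
        for method in ("pls", "pcr"):
            assert hs.select_n_components(X, y, method, max_pc=10) == 3

    def test_pure_noise_prefers_one_component(self):
        """Under the null, LOO error grows with k, so ties break to k=1."""
        hits = 0
        for seed in range(15):
            g = np.random.default_rng(seed)
            X = g.standard_normal((30, 20))
            y = g.standard_normal(30)
            k = hs.select_n_components(X, y, "pls", max_pc=8)
            hits += (k == 1)
        assert hits >= 10

    def test_forced_single_component(self, rng):
        X = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        assert hs.select_n_components(X, y, "pls", max_pc=1) == 1

    def test_loo_predictions_match_explicit_refits(self, rng):
        """The fast all-k LOO path equals naive per-fold refits."""
        X = rng.standard_normal((15, 8))
        y = X @ rng.standard_normal(8) + 0.1 * rng.standard_normal(15)
        preds = _loo_predictions_all_k(X, y, "pls", 4)
        for i in range(15):
            mask = np.ones(15, dtype=bool)
            mask[i] = False
            for k in range(1, 5):
                model = hs.fit_pls(X[mask], y[mask], k)
                assert preds[i, k - 1] == pytest.approx(
                    hs.predict(model, X[i][None, :])[0], abs=1e-8)
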