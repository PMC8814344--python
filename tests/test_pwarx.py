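"""Tests of the PWARX identification stage: clustering, boundaries, least
squares, prediction, fit percentage and the switching/whiteness diagnostics."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stancefit.cohort import TruePWARX, default_true_pwarx, generate_pwarx_data
from stancefit.pwarx import (
    IdentifyConfig,
    PWARXModel,
    check_continuity,
    fit_arx_submodels,
    fit_boundary,
    fit_percent,
    identify,
    predict,
    predict_region,
    residual_acf,
    silhouette_select,
    spectral_cluster,
    switching_signal,
)
from stancefit.regressors import LagCoordinate, RegressionDataset


def _blobs(rng, centers, n_per=30, sd=0.4):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(np.asarray(c) + sd * rng.standard_normal((n_per, len(c))))
        labels.extend([i] * n_per)
    return np.vstack(pts), np.array(labels)


def _dataset(X, y, groups=None):
    cols = [LagCoordinate("theta", i + 1) for i in range(X.shape[1])]
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    return RegressionDataset(X=X, y=y, columns=cols, groups=np.asarray(groups))


def _two_region_model(b=0.0):
    """s = 2 model split by x0 <=> -b with distinct affine maps."""
    return PWARXModel(
        submodels=np.array([[2.0, 0.5, 1.0], [-1.0, 3.0, -2.0]]),
        boundaries=np.array([[1.0, 0.0, b]]),
        columns=[LagCoordinate("theta", 1), LagCoordinate("theta", 2)],
        s=2,
    )


class TestSpectralCluster:
    def test_separated_blobs_recovered(self, rng):
        X, truth = _blobs(rng, [(0, 0), (8, 8)])
        labels = spectral_cluster(X, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n(self):
        X = np.arange(10.0).reshape(5, 2)
        assert sorted(spectral_cluster(X, 5, seed=0)) == list(range(5))

    def test_same_seed_same_labels(self, rng):
        X, _ = _blobs(rng, [(0, 0), (5, 5), (0, 5)], n_per=20)
        np.testing.assert_array_equal(spectral_cluster(X, 3, seed=4),
                                      spectral_cluster(X, 3, seed=4))

    def test_errors(self):
        with pytest.raises(ValueError):
            spectral_cluster(np.zeros((4, 2)), 5, seed=0)
        with pytest.raises(ValueError):
            spectral_cluster(np.ones((6, 2)), 2, seed=0)   # identical points


class TestSilhouetteSelect:
    def test_two_blobs(self, rng):
        X, _ = _blobs(rng, [(0, 0), (10, 0)])
        assert silhouette_select(X, seed=0) == 2

    def test_three_blobs_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X, _ = _blobs(rng, [(0, 0), (10, 0), (5, 9)], sd=0.5)
            hits += silhouette_select(X, seed=seed) == 3
        assert hits >= 9

    def test_singleton_range(self, rng):
        X, _ = _blobs(rng, [(0, 0), (10, 0), (5, 9)])
        assert silhouette_select(X, k_range=(2,), seed=0) == 2

    def test_range_shrinks_with_warning(self, rng, caplog):
        X = rng.standard_normal((5, 2))
        with caplog.at_level("WARNING"):
            silhouette_select(X, k_range=(2, 6), seed=0)
        assert any("shrinking" in r.message for r in caplog.records)

    def test_invalid_range(self, rng):
        with pytest.raises(ValueError):
            silhouette_select(rng.standard_normal((20, 2)), k_range=(1, 2))


class TestFitBoundary:
    def test_separable_classes_fully_split(self, rng):
        X, labels = _blobs(rng, [(-3, 0), (3, 0)], n_per=50)
        H = fit_boundary(X, labels)
        assert H.shape == (1, 3)
        side = X @ H[0, :-1] + H[0, -1]
        assert np.all(side[labels == 0] <= 0) and np.all(side[labels == 1] > 0)

    def test_label_flip_negates_normal(self, rng):
        X, labels = _blobs(rng, [(-3, 0), (3, 0)], n_per=50)
        H = fit_boundary(X, labels)
        Hf = fit_boundary(X, 1 - labels)
        cos = np.dot(H[0], -Hf[0]) / (np.linalg.norm(H[0]) * np.linalg.norm(Hf[0]))
        assert cos > 0.999

    def test_noisy_hyperplane_direction(self):
        rng = np.random.default_rng(7)
        n = 500
        X = rng.standard_normal((n, 2))
        w_true = np.array([1.0, -1.0]) / np.sqrt(2)
        labels = (X @ w_true + 0.3 > 0).astype(int)
        flip = rng.random(n) < 0.05
        labels[flip] = 1 - labels[flip]
        H = fit_boundary(X, labels)
        est = H[0] / np.linalg.norm(H[0])
        ref = np.array([w_true[0], w_true[1], 0.3])
        ref /= np.linalg.norm(ref)
        assert abs(np.dot(est, ref)) > 0.98

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_boundary(rng.standard_normal((20, 2)), np.zeros(20))


class TestFitArxSubmodels:
    def test_noiseless_single_region_exact(self, rng):
        X = rng.standard_normal((60, 3))
        theta = np.array([0.5, -1.2, 0.3, 2.0])
        y = X @ theta[:-1] + theta[-1]
        model = fit_arx_submodels(_dataset(X, y), np.zeros(60, dtype=int), None)
        np.testing.assert_allclose(model.submodels[0], theta, atol=1e-10)
        assert model.noise_sd_hat == pytest.approx(0.0, abs=1e-10)

    def test_two_regions_with_true_labels(self, rng):
        X = rng.standard_normal((200, 2))
        labels = (X[:, 0] > 0).astype(int)
        thetas = np.array([[1.0, -0.5, 0.2], [-2.0, 0.3, 1.5]])
        A = np.column_stack([X, np.ones(200)])
        y = np.einsum("ij,ij->i", A, thetas[labels])
        H = np.array([[1.0, 0.0, 0.0]])
        model = fit_arx_submodels(_dataset(X, y), labels, H)
        np.testing.assert_allclose(model.submodels, thetas, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((80, 4))
        y = rng.standard_normal(80)
        model = fit_arx_submodels(_dataset(X, y), np.zeros(80, dtype=int), None)
        A = np.column_stack([X, np.ones(80)])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(model.submodels[0], oracle, atol=1e-9)

    def test_rank_deficient_minimum_norm(self):
        X = np.column_stack([np.ones(30), np.ones(30)])   # duplicate columns
        y = 3.0 * np.ones(30)
        model = fit_arx_submodels(_dataset(X, y), np.zeros(30, dtype=int), None)
        pred = np.column_stack([X, np.ones(30)]) @ model.submodels[0]
        np.testing.assert_allclose(pred, y, atol=1e-9)
        assert np.all(np.isfinite(model.submodels))

    def test_starved_region_named(self, rng):
        X = rng.standard_normal((50, 3))
        labels = np.zeros(50, dtype=int)
        labels[:2] = 1
        with pytest.raises(ValueError, match="region 1 starved"):
            fit_arx_submodels(_dataset(X, rng.standard_normal(50)), labels, None)

    def test_empty_region_vs_declared_s(self, rng):
        X = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="empty"):
            fit_arx_submodels(_dataset(X, rng.standard_normal(50)),
                              np.zeros(50, dtype=int), None, s=2)

    def test_boundary_points_discarded(self, rng):
        X = rng.standard_normal((100, 2))
        X[:5, 0] = 0.0                       # exactly on the hyperplane
        labels = (X[:, 0] > 0).astype(int)
        thetas = np.array([[1.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        A = np.column_stack([X, np.ones(100)])
        y = np.einsum("ij,ij->i", A, thetas[labels])
        y[:5] = 99.0                          # poisoned rows must be ignored
        H = np.array([[1.0, 0.0, 0.0]])
        model = fit_arx_submodels(_dataset(X, y), labels, H)
        np.testing.assert_allclose(model.submodels, thetas, atol=1e-9)


class TestIdentify:
    def test_recovers_known_two_region_model(self):
        truth = default_true_pwarx()
        ds, _ = generate_pwarx_data(truth, 600, seed=11, input_process="margin")
        model = identify(ds, IdentifyConfig(k_range=(2, 3), seed=0))
        assert model.s == 2
        # align sub-models by affine offset sign (the truth has +6 / -6)
        order = np.argsort(-model.submodels[:, -1])
        np.testing.assert_allclose(model.submodels[order], truth.coeffs, atol=1e-5)
        w = model.boundaries[0, :-1]
        cos = abs(w[0]) / np.linalg.norm(w)
        assert cos > 0.999
        assert set(model.silhouette) == {2, 3}

    def test_empty_training_set(self):
        ds = _dataset(np.empty((0, 2)), np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            identify(ds)

    def test_stage_tagged_failure(self):
        # all regression vectors identical: the affinity scale collapses
        ds = _dataset(np.ones((30, 2)), np.ones(30))
        with pytest.raises(RuntimeError, match="clustering stage"):
            identify(ds)


class TestPredict:
    def test_single_region_affine(self):
        model = PWARXModel(submodels=np.array([[2.0, -1.0, 0.5]]), boundaries=None,
                           columns=[LagCoordinate("theta", 1),
                                    LagCoordinate("theta", 2)], s=1)
        np.testing.assert_allclose(predict(model, np.array([[1.0, 2.0]])),
                                   [2.0 - 2.0 + 0.5])
        np.testing.assert_array_equal(predict_region(model, np.zeros((3, 2))), 0)

    def test_boundary_point_goes_to_lower_region(self):
        model = _two_region_model()
        assert predict_region(model, np.array([[0.0, 1.0]]))[0] == 0
        assert predict_region(model, np.array([[-0.5, 0.0]]))[0] == 0
        assert predict_region(model, np.array([[0.5, 0.0]]))[0] == 1

    def test_piecewise_affine_values(self):
        model = _two_region_model()
        X = np.array([[-1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        got = predict(model, X)
        np.testing.assert_allclose(got, [2 * -1 + 0.5 * 1 + 1.0,
                                         2 * 0 + 0.5 * 1 + 1.0,
                                         -1 * 1 + 3 * 1 - 2.0])

    def test_matches_generator_on_noiseless_data(self):
        truth = default_true_pwarx()
        model = PWARXModel(submodels=truth.coeffs,
                           boundaries=truth.hyperplane[None, :],
                           columns=[LagCoordinate("theta", i + 1) for i in range(5)],
                           s=2)
        ds, _ = generate_pwarx_data(truth, 300, seed=3, input_process="margin")
        np.testing.assert_allclose(predict(model, ds.X), ds.y, atol=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict(_two_region_model(), np.zeros((4, 3)))


class TestFitPercent:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(50)
        assert fit_percent(y, y) == 100.0

    def test_mean_prediction_is_zero(self, rng):
        y = rng.standard_normal(50)
        assert fit_percent(y, np.full(50, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_half_variance_worked_value(self):
        y = np.array([0.0, 2.0])              # ||y - mean|| = sqrt(2)
        y_hat = np.array([0.0, 1.0])          # ||y - y_hat|| = 1
        expected = 100.0 * (1.0 - 1.0 / np.sqrt(2))
        assert fit_percent(y, y_hat) == pytest.approx(expected, abs=1e-9)
        assert fit_percent(y, y_hat) == pytest.approx(29.289321881345245, abs=1e-9)

    def test_never_exceeds_100(self, rng):
        for _ in range(20):
            y = rng.standard_normal(30)
            y_hat = y + rng.standard_normal(30)
            assert fit_percent(y, y_hat) <= 100.0

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_percent(np.ones(5), np.ones(5))          # constant target
        with pytest.raises(ValueError):
            fit_percent(np.arange(4.0), np.arange(3.0))  # length mismatch


class TestSwitchingSignal:
    def test_no_switch_when_one_side(self):
        model = _two_region_model()
        X = np.column_stack([np.full(30, -1.0), np.zeros(30)])
        sig = switching_signal(model, _dataset(X, np.zeros(30), groups=np.ones(30)))
        assert sig[1].switch_count == 0
        assert sig[1].first_switch_time is None
        assert np.all(sig[1].sigma == 1)

    def test_alternating_regions(self):
        model = _two_region_model()
        x0 = np.where(np.arange(20) % 2 == 0, -1.0, 1.0)
        X = np.column_stack([x0, np.zeros(20)])
        sig = switching_signal(model, _dataset(X, np.zeros(20), groups=np.ones(20)))
        assert sig[1].switch_count == 19

    def test_single_crossing_time_within_30ms(self):
        # regressor ramps through the hyperplane x0 = 0.305 between rows 30
        # and 31, i.e. at 0.50-0.51 s after onset with max_lag = 20
        model = _two_region_model(b=-0.305)
        x0 = 0.01 * np.arange(100)
        X = np.column_stack([x0, np.zeros(100)])
        sig = switching_signal(model, _dataset(X, np.zeros(100), groups=np.ones(100)))
        assert sig[1].switch_count == 1
        assert abs(sig[1].first_switch_time - 0.51) <= 0.03

    def test_time_axis_offsets_by_max_lag(self):
        model = _two_region_model()
        X = np.column_stack([np.full(10, -1.0), np.zeros(10)])
        sig = switching_signal(model, _dataset(X, np.zeros(10), groups=np.ones(10)))
        np.testing.assert_allclose(sig[1].time, (20 + np.arange(10)) / 100.0)

    def test_multiple_subjects_split(self):
        model = _two_region_model()
        X = np.column_stack([np.full(8, -1.0), np.zeros(8)])
        groups = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        sig = switching_signal(model, _dataset(X, np.zeros(8), groups=groups))
        assert set(sig) == {1, 2}
        assert sig[2].sigma.size == 4

    def test_non_contiguous_rows_rejected(self):
        model = _two_region_model()
        X = np.zeros((4, 2))
        groups = np.array([1, 2, 1, 2])
        with pytest.raises(ValueError, match="contiguous"):
            switching_signal(model, _dataset(X, np.zeros(4), groups=groups))


class TestResidualAcf:
    def test_white_noise_mostly_inside_band(self):
        frac_ok = []
        for seed in range(5):
            r = np.random.default_rng(seed).standard_normal(1000)
            vals, band = residual_acf(r, max_lag=20)
            frac_ok.append(np.mean(np.abs(vals[1:]) <= band))
        assert np.mean(frac_ok) >= 0.93

    def test_lag_zero_is_one(self, rng):
        vals, _ = residual_acf(rng.standard_normal(500))
        assert vals[0] == pytest.approx(1.0)

    def test_ar1_exceeds_band_at_lag_one(self, rng):
        n, phi = 2000, 0.9
        r = np.empty(n)
        r[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            r[i] = phi * r[i - 1] + eps[i]
        vals, band = residual_acf(r)
        assert vals[1] > band
        assert vals[1] == pytest.approx(phi, abs=0.1)

    def test_band_formula(self, rng):
        _, band = residual_acf(rng.standard_normal(400))
        assert band == pytest.approx(1.96 / np.sqrt(400))

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            residual_acf(rng.standard_normal(10), max_lag=20)
        with pytest.raises(ValueError):
            residual_acf(np.ones(100))


class TestCheckContinuity:
    def test_identical_submodels(self):
        model = PWARXModel(submodels=np.array([[1.0, 2.0], [1.0, 2.0]]),
                           boundaries=np.array([[1.0, 0.0]]),
                           columns=[LagCoordinate("theta", 1)], s=2)
        assert check_continuity(model, np.array([[0.3], [-0.7]])) == 0.0

    def test_continuous_construction(self):
        # theta_1 - theta_2 proportional to [w, b]: the affine maps agree
        # exactly on the hyperplane w.x + b = 0
        w, b = np.array([1.0, -2.0]), 0.5
        base = np.array([0.4, 1.1, -0.3])
        other = base + 3.0 * np.concatenate([w, [b]])
        model = PWARXModel(submodels=np.vstack([base, other]),
                           boundaries=np.concatenate([w, [b]])[None, :],
                           columns=[LagCoordinate("theta", 1),
                                    LagCoordinate("theta", 2)], s=2)
        # points on the boundary: x1 = (w0 x0 + b)/2
        x0 = np.linspace(-2, 2, 9)
        pts = np.column_stack([x0, (w[0] * x0 + b) / 2.0])
        assert check_continuity(model, pts) < 1e-9

    def test_generic_discontinuity(self):
        model = _two_region_model()
        pts = np.array([[0.0, 1.0]])
        assert check_continuity(model, pts) > 0.1

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            check_continuity(_two_region_model(), np.empty((0, 2)))
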