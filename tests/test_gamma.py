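"""Class-ellipsoid construction and the gamma separability score."""

import numpy as np
import pytest

from gammafs import (GammaEvaluator, LabeledDataset, ellipsoid_radius,
                     estimate_class_ellipsoid, gamma_metric, pair_gamma)
from gammafs.gamma import ClassEllipsoid, _decompose

from conftest import random_psd, random_unit


def make_ellipsoid(centroid, cov, class_id=1, n_k=10):
    lam, U = _decompose(np.asarray(cov, dtype=float))
    return ClassEllipsoid(class_id=class_id, centroid=np.asarray(centroid, float),
                          covariance=np.asarray(cov, float), eigenvalues=lam,
                          eigenvectors=U, estimator="empirical", n_k=n_k)


def dataset_from_class_values(values_by_class):
    X = np.vstack([np.atleast_2d(v).T if np.ndim(v) == 1 else v
                   for v in values_by_class])
    y = np.concatenate([np.full(len(v), k + 1) for k, v in enumerate(values_by_class)])
    return LabeledDataset(np.atleast_2d(X), y)


class TestEstimateClassEllipsoid:
    def test_one_dimensional_mean_and_variance(self):
        data = dataset_from_class_values([[1.0, 2.0, 3.0], [5.0, 6.0]])
        e = estimate_class_ellipsoid(data, 1, [0], estimator="empirical")
        assert e.centroid == pytest.approx([2.0])
        assert e.covariance == pytest.approx(np.array([[1.0]]))
        assert e.estimator == "empirical"

    def test_auto_switches_to_shrinkage_and_is_positive_definite(self, rng):
        X = rng.standard_normal((25, 10))
        y = np.array([1] * 5 + [2] * 20)
        data = LabeledDataset(X, y)
        e = estimate_class_ellipsoid(data, 2, list(range(10)), estimator="auto")
        assert e.estimator == "shrinkage"   # triggered by the smaller class
        assert np.linalg.eigvalsh(e.covariance).min() > 0

    def test_collinear_columns_clip_to_zero_eigenvalue(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2.0 * x])
        X = np.vstack([X, rng.standard_normal((10, 2)) + 5])
        y = np.array([1] * 30 + [2] * 10)
        e = estimate_class_ellipsoid(LabeledDataset(X, y), 1, [0, 1], "empirical")
        assert e.eigenvalues.min() == 0.0

    def test_eigen_reconstruction_and_orthonormality(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.array([1] * 30 + [2] * 30)
        e = estimate_class_ellipsoid(LabeledDataset(X, y), 1, [0, 1, 2, 3], "empirical")
        rebuilt = e.eigenvectors @ np.diag(e.eigenvalues) @ e.eigenvectors.T
        assert rebuilt == pytest.approx(e.covariance, abs=1e-8)
        assert e.eigenvectors.T @ e.eigenvectors == pytest.approx(np.eye(4), abs=1e-8)
        assert np.all(np.diff(e.eigenvalues) <= 0)

    def test_errors(self, two_class_blobs):
        with pytest.raises(ValueError):
            estimate_class_ellipsoid(two_class_blobs, 9, [0])
        with pytest.raises(ValueError):
            estimate_class_ellipsoid(two_class_blobs, 1, [])
        with pytest.raises(ValueError):
            estimate_class_ellipsoid(two_class_blobs, 1, [0], estimator="magic")


class TestEllipsoidRadius:
    def test_sphere(self):
        e = make_ellipsoid([0, 0, 0], np.eye(3))
        assert ellipsoid_radius(e, [1, 0, 0]) == pytest.approx(1.0)
        assert ellipsoid_radius(e, np.ones(3) / np.sqrt(3)) == pytest.approx(1.0)

    def test_axis_aligned(self):
        e = make_ellipsoid([0, 0], np.diag([4.0, 1.0]))
        assert ellipsoid_radius(e, [1, 0]) == pytest.approx(2.0)
        assert ellipsoid_radius(e, [0, 1]) == pytest.approx(1.0)

    def test_scale_knob(self):
        e = make_ellipsoid([0, 0], np.diag([4.0, 1.0]))
        assert ellipsoid_radius(e, [1, 0], scale=2.0) == pytest.approx(4.0)

    def test_quadratic_form_oracle(self, rng):
        # support radius must equal sqrt(d' W d) for any PSD W and unit d
        for _ in range(1000):
            d = rng.integers(2, 6)
            W = random_psd(rng, d)
            u = random_unit(rng, d)
            e = make_ellipsoid(np.zeros(d), W)
            assert ellipsoid_radius(e, u) == pytest.approx(
                np.sqrt(u @ W @ u), abs=1e-10)

    def test_non_unit_direction_rejected(self):
        e = make_ellipsoid([0, 0], np.eye(2))
        with pytest.raises(ValueError):
            ellipsoid_radius(e, [1.0, 1.0])


class TestPairGamma:
    def test_separated_spheres(self):
        e1 = make_ellipsoid([0, 0], np.eye(2))
        e2 = make_ellipsoid([10, 0], np.eye(2))
        assert pair_gamma(e1, e2) == pytest.approx(8.0)

    def test_identical_ellipsoids_fully_overlap(self):
        e = make_ellipsoid([1, 2], np.eye(2))
        assert pair_gamma(e, e) == pytest.approx(-2.0)

    def test_anisotropic_pair(self):
        e1 = make_ellipsoid([0, 0], np.diag([4.0, 1.0]))
        e2 = make_ellipsoid([4, 0], np.eye(2))
        assert pair_gamma(e1, e2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            W1, W2 = random_psd(rng, 3), random_psd(rng, 3)
            m1, m2 = rng.standard_normal(3), rng.standard_normal(3)
            e1, e2 = make_ellipsoid(m1, W1), make_ellipsoid(m2, W2)
            assert pair_gamma(e1, e2) == pair_gamma(e2, e1)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pair_gamma(make_ellipsoid([0], [[1.0]]), make_ellipsoid([0, 0], np.eye(2)))


class TestGammaMetric:
    def test_three_class_total_is_pair_sum(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) + mu
                       for mu in ([0, 0], [5, 0], [0, 5])])
        y = np.repeat([1, 2, 3], 20)
        data = LabeledDataset(X, y)
        g = gamma_metric(data, [0, 1], estimator="empirical")
        assert set(g.pairwise) == {(1, 2), (1, 3), (2, 3)}
        assert g.total == pytest.approx(sum(g.pairwise.values()))

    def test_sign_conventions(self, rng, two_class_blobs):
        # far-apart classes: positive; identical class laws: negative
        assert gamma_metric(two_class_blobs, [0, 1, 2]).total > 0
        X = rng.standard_normal((2000, 2))
        y = np.array([1, 2] * 1000)
        assert gamma_metric(LabeledDataset(X, y), [0, 1]).total < 0

    def test_translation_invariance(self, two_class_blobs):
        base = gamma_metric(two_class_blobs, [0, 1, 2]).total
        shifted = LabeledDataset(two_class_blobs.features + np.array([3.0, -7.0, 100.0]),
                                 two_class_blobs.labels)
        assert gamma_metric(shifted, [0, 1, 2]).total == pytest.approx(base, abs=1e-8)

    def test_rotation_invariance(self, rng, two_class_blobs):
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = LabeledDataset(two_class_blobs.features @ Q.T, two_class_blobs.labels)
        assert gamma_metric(rotated, [0, 1, 2]).total == pytest.approx(
            gamma_metric(two_class_blobs, [0, 1, 2]).total, abs=1e-6)

    def test_observation_order_invariance(self, rng, two_class_blobs):
        perm = rng.permutation(two_class_blobs.n)
        shuffled = LabeledDataset(two_class_blobs.features[perm],
                                  two_class_blobs.labels[perm])
        assert gamma_metric(shuffled, [0, 1, 2]).total == pytest.approx(
            gamma_metric(two_class_blobs, [0, 1, 2]).total, abs=1e-10)

    def test_label_permutation_destroys_separability(self, rng, two_class_blobs):
        base = gamma_metric(two_class_blobs, [0, 1, 2]).total
        worse = 0
        for _ in range(50):
            y = rng.permutation(two_class_blobs.labels)
            if gamma_metric(LabeledDataset(two_class_blobs.features, y),
                            [0, 1, 2]).total < base:
                worse += 1
        assert worse == 50

    def test_shrinkage_guard_small_class(self, rng):
        X = rng.standard_normal((24, 12))
        y = np.array([1] * 6 + [2] * 18)
        data = LabeledDataset(X, y)
        for k in (1, 2):
            e = estimate_class_ellipsoid(data, k, list(range(12)), "auto")
            assert e.estimator == "shrinkage"
            assert np.linalg.eigvalsh(e.covariance).min() > 0
        assert np.isfinite(gamma_metric(data, list(range(12))).total)


class TestGammaEvaluator:
    @pytest.mark.parametrize("estimator", ["empirical", "shrinkage", "auto"])
    def test_matches_reference_path(self, rng, estimator):
        X = rng.standard_normal((40, 8))
        y = np.array([1] * 12 + [2] * 28)
        data = LabeledDataset(X, y)
        ev = GammaEvaluator(data, estimator=estimator)
        for _ in range(20):
            d = rng.integers(1, 9)
            subset = sorted(rng.choice(8, size=d, replace=False).tolist())
            ref = gamma_metric(data, subset, estimator=estimator).total
            assert ev(subset) == pytest.approx(ref, abs=1e-9)

    def test_scale_consistency(self, two_class_blobs):
        ev = GammaEvaluator(two_class_blobs, scale=2.5)
        ref = gamma_metric(two_class_blobs, [0, 2], scale=2.5).total
        assert ev([0, 2]) == pytest.approx(ref, abs=1e-9)
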