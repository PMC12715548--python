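"""Tests for the MIND estimators: closed-form oracle, k-NN estimator, matrix."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import factorscape as fs
from factorscape.matrices import lower_triangle
from factorscape.mind import VertexFeatureTable


def _table_from_gaussians(params, n=200, seed=0, feature_names=None):
    """Build a VertexFeatureTable by sampling the given (mean, cov) per region."""
    rng = np.random.default_rng(seed)
    regions = [f"r{i}" for i in range(len(params))]
    f = len(np.atleast_1d(params[0][0]))
    data = {}
    for name, (mu, cov) in zip(regions, params):
        data[name] = rng.multivariate_normal(np.atleast_1d(mu), np.atleast_2d(cov), size=n)
    return VertexFeatureTable(
        regions=regions, features=feature_names or [f"f{i}" for i in range(f)], data=data
    )


class TestZscoreFeatures:
    def test_pooled_moments(self):
        table, _ = fs.gen_vertex_features(5, 50, 3, seed=1)
        z = fs.zscore_features(table)
        pooled = z.pooled()
        assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(pooled.std(axis=0), 1.0, atol=1e-10)

    def test_idempotent(self):
        table, _ = fs.gen_vertex_features(5, 50, 3, seed=2)
        z1 = fs.zscore_features(table)
        z2 = fs.zscore_features(z1)
        for r in z1.regions:
            assert np.allclose(z1.data[r], z2.data[r], atol=1e-10)

    def test_constant_feature_named_in_error(self):
        table, _ = fs.gen_vertex_features(3, 30, 2, seed=3)
        for r in table.regions:
            table.data[r][:, 1] = 5.0
        with pytest.raises(ValueError, match=table.features[1]):
            fs.zscore_features(table)


class TestGaussianKL:
    def test_identical_distributions_zero(self):
        mu, cov = np.array([1.0, -2.0]), np.array([[2.0, 0.3], [0.3, 1.0]])
        assert fs.gaussian_kl(mu, cov, mu, cov) == pytest.approx(0.0, abs=1e-14)

    def test_unit_variance_mean_shift_closed_form(self):
        # 1-D equal unit variances: KL = (mu1 - mu2)^2 / 2
        assert fs.gaussian_kl([0.0], [[1.0]], [1.0], [[1.0]]) == pytest.approx(0.5)
        assert fs.gaussian_kl([0.0], [[1.0]], [2.0], [[1.0]]) == pytest.approx(2.0)

    def test_asymmetric_for_unequal_covariances(self):
        m = np.zeros(2)
        c1 = np.eye(2)
        c2 = np.diag([4.0, 1.0])
        fwd = fs.gaussian_kl(m, c1, m, c2)
        rev = fs.gaussian_kl(m, c2, m, c1)
        assert fwd != pytest.approx(rev)
        # both directions match the diagonal-Gaussian closed form
        # KL = 0.5 * sum(s1/s2 - 1 + ln(s2/s1))
        def diag_kl(s1, s2):
            s1, s2 = np.asarray(s1), np.asarray(s2)
            return 0.5 * np.sum(s1 / s2 - 1.0 + np.log(s2 / s1))

        assert fwd == pytest.approx(diag_kl([1, 1], [4, 1]), abs=1e-12)
        assert rev == pytest.approx(diag_kl([4, 1], [1, 1]), abs=1e-12)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.standard_normal((3, 3))
            b = rng.standard_normal((3, 3))
            kl = fs.gaussian_kl(
                rng.standard_normal(3), a @ a.T + np.eye(3),
                rng.standard_normal(3), b @ b.T + np.eye(3),
            )
            assert kl >= -1e-12

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            fs.gaussian_kl([0, 0], np.zeros((2, 2)), [0, 0], np.eye(2))


class TestKnnKL:
    def test_matching_distributions_near_zero(self, rng):
        x = rng.standard_normal((2000, 3))
        y = rng.standard_normal((2000, 3))
        assert fs.knn_kl_estimate(x, y, k=3) < 0.05

    def test_one_dimensional_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=(2000, 1))
        y = rng.normal(1.0, 1.0, size=(2000, 1))
        assert fs.knn_kl_estimate(x, y, k=3) == pytest.approx(0.5, abs=0.15)

    def test_identical_sample_sets_clamped_to_zero(self, rng):
        x = rng.standard_normal((200, 2))
        assert fs.knn_kl_estimate(x, x.copy(), k=3) == 0.0

    def test_k_too_large_rejected(self, rng):
        x = rng.standard_normal((10, 2))
        y = rng.standard_normal((50, 2))
        with pytest.raises(ValueError, match="k="):
            fs.knn_kl_estimate(x, y, k=10)

    def test_duplicate_points_deterministic(self, rng):
        x = np.repeat(rng.standard_normal((50, 2)), 2, axis=0)
        y = rng.standard_normal((100, 2))
        a = fs.knn_kl_estimate(x, y, k=3)
        b = fs.knn_kl_estimate(x, y, k=3)
        assert a == b and np.isfinite(a)

    def test_consistency_error_shrinks_with_samples(self):
        # median absolute error against the closed form decreases with n
        mu2 = np.array([1.0, 0.0])
        true = fs.gaussian_kl(np.zeros(2), np.eye(2), mu2, np.eye(2))
        errs = []
        for n in (200, 1000, 5000):
            per_seed = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                x = rng.standard_normal((n, 2))
                y = mu2 + rng.standard_normal((n, 2))
                per_seed.append(abs(fs.knn_kl_estimate(x, y, k=3) - true))
            errs.append(np.median(per_seed))
        assert errs[0] > errs[1] > errs[2]


class TestMindMatrix:
    def test_transform_arithmetic(self):
        # D=0 -> MIND=1 and D=1 -> MIND=0.5 via the definition on fitted pairs
        params = [(np.zeros(2), np.eye(2)), (np.zeros(2), np.eye(2))]
        table = _table_from_gaussians(params, n=4000, seed=4)
        sm = fs.mind_matrix(table, estimator="gaussian", standardize=False)
        assert sm.values[0, 1] == pytest.approx(1.0, abs=0.01)
        # symmetrized KL of 1 from a sqrt(2) mean shift at unit variance
        params = [(np.zeros(1), np.eye(1)), (np.array([np.sqrt(2.0)]), np.eye(1))]
        table = _table_from_gaussians(params, n=20000, seed=5)
        sm = fs.mind_matrix(table, estimator="gaussian", standardize=False)
        assert sm.values[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_range_and_diagonal(self):
        table, _ = fs.gen_vertex_features(8, 60, 3, seed=6)
        sm = fs.mind_matrix(table, estimator="gaussian")
        tri = sm.lower_triangle()
        assert np.all((tri > 0) & (tri <= 1))
        assert np.allclose(np.diag(sm.values), 1.0)

    def test_recovery_small_cohort(self):
        table, true_kl = fs.gen_vertex_features(10, 200, 5, separation=1.0, seed=7)
        sm = fs.mind_matrix(table, estimator="gaussian")
        truth = 1.0 / (1.0 + true_kl)
        r = spearmanr(sm.lower_triangle(), lower_triangle(truth)).statistic
        assert r > 0.9

    def test_monotone_in_true_divergence(self):
        # growing the mean shift of one pair never increases its MIND value
        vals = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            params = [
                (np.zeros(2), np.eye(2)),
                (np.array([shift, 0.0]), np.eye(2)),
                (np.array([0.0, 3.0]), np.eye(2)),
            ]
            table = _table_from_gaussians(params, n=2000, seed=8)
            sm = fs.mind_matrix(table, estimator="gaussian", standardize=False)
            vals.append(sm.values[0, 1])
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_region_permutation_equivariance(self):
        table, _ = fs.gen_vertex_features(6, 80, 3, seed=9)
        sm = fs.mind_matrix(table, estimator="gaussian")
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = VertexFeatureTable(
            regions=[table.regions[i] for i in perm],
            features=list(table.features),
            data=dict(table.data),
        )
        sm_p = fs.mind_matrix(shuffled, estimator="gaussian")
        assert np.allclose(sm_p.values, sm.values[np.ix_(perm, perm)], atol=1e-10)

    def test_znorm_statistics(self):
        table, _ = fs.gen_vertex_features(10, 60, 3, seed=10)
        sm = fs.mind_matrix(table, estimator="gaussian", znorm=True)
        tri = sm.lower_triangle()
        assert sm.kind == "mind_znorm"
        assert tri.mean() == pytest.approx(0.0, abs=1e-10)
        assert tri.std() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(np.diag(sm.values), tri.max())

    def test_knn_and_gaussian_agree_on_gaussian_data(self):
        table, true_kl = fs.gen_vertex_features(6, 400, 3, separation=1.0, seed=11)
        g = fs.mind_matrix(table, estimator="gaussian")
        k = fs.mind_matrix(table, estimator="knn", k=3)
        r = np.corrcoef(g.lower_triangle(), k.lower_triangle())[0, 1]
        assert r > 0.9
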