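"""Tests for correspondence, behavior, PCA, receptor regression and spin null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import factorscape as fs
from factorscape.matrices import from_lower_triangle, lower_triangle
from factorscape.spin import _greedy_unique_assignment, _hungarian_assignment
from factorscape.synthetic import ReceptorAtlas


def _pearson_direct(x, y):
    """Direct-summation covariance-formula oracle for Pearson r."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


class TestLowerTriangle:
    @pytest.mark.parametrize("r, length", [(3, 3), (20, 190), (400, 79800)])
    def test_vector_length(self, r, length):
        m = np.zeros((r, r))
        assert lower_triangle(m).shape == (length,)

    def test_round_trip(self, rng):
        a = rng.standard_normal((6, 6))
        a = a + a.T
        np.fill_diagonal(a, 0.0)
        assert np.array_equal(from_lower_triangle(lower_triangle(a)), a)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            lower_triangle(np.zeros((3, 4)))


class TestFactorCorrespondence:
    def test_self_and_negation(self, small_factors):
        tbl = fs.factor_correspondence([small_factors[0]], [small_factors[0], -small_factors[0]])
        assert tbl.r.iloc[0] == pytest.approx(1.0)
        assert tbl.r.iloc[1] == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(50):
            a = rng.standard_normal((8, 8))
            a = a + a.T
            b = rng.standard_normal((8, 8))
            b = b + b.T
            tbl = fs.factor_correspondence([a], [b])
            oracle = _pearson_direct(lower_triangle(a).tolist(), lower_triangle(b).tolist())
            assert tbl.r.iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_up_to_transposition(self, small_factors):
        ab = fs.factor_correspondence(small_factors[:2], small_factors[1:])
        ba = fs.factor_correspondence(small_factors[1:], small_factors[:2])
        pivot_ab = ab.pivot(index="a", columns="b", values="r").to_numpy()
        pivot_ba = ba.pivot(index="a", columns="b", values="r").to_numpy()
        assert np.allclose(pivot_ab, pivot_ba.T, atol=1e-14)


class TestLoadingBehavior:
    def test_perfect_coupling(self, small_cohort):
        _, loadings = small_cohort
        beh = pd.DataFrame({"s": loadings[:, 0]})
        tbl = fs.loading_behavior_correlations(loadings, beh)
        cell = tbl[(tbl.factor == "factor_1") & (tbl.scale == "s")]
        assert cell.r.item() == pytest.approx(1.0)

    def test_pairwise_deletion_bookkeeping(self, small_cohort):
        _, loadings = small_cohort
        y = loadings[:, 0].copy()
        y[: len(y) // 2] = np.nan
        tbl = fs.loading_behavior_correlations(loadings, pd.DataFrame({"s": y}))
        assert (tbl.n == len(y) - len(y) // 2).all()

    def test_underpowered_cell_flagged(self, small_cohort):
        _, loadings = small_cohort
        y = np.full(len(loadings), np.nan)
        y[:2] = [1.0, 2.0]
        tbl = fs.loading_behavior_correlations(loadings, pd.DataFrame({"s": y}))
        assert tbl.r.isna().all()
        assert (tbl.n == 2).all()

    def test_type_one_error_calibrated_under_null(self):
        # zero-effect behavior: rejection rate at alpha=.05 near nominal
        rej = total = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            loadings = rng.dirichlet([0.5] * 3, 80)
            y = rng.standard_normal(80)
            tbl = fs.loading_behavior_correlations(loadings, pd.DataFrame({"s": y}))
            rej += int((tbl.p < 0.05).iloc[0])
            total += 1
        assert 0.03 <= rej / total <= 0.075


class TestPcaFirstComponent:
    def test_rank_one_recovers_direction(self, rng):
        v = rng.standard_normal(12)
        pc = fs.pca_first_component(np.outer(v, v))
        r = abs(np.corrcoef(pc, v)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, small_factors):
        for m in small_factors:
            pc = fs.pca_first_component(m)
            assert np.corrcoef(pc, m.mean(axis=1))[0, 1] >= 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance|rank"):
            fs.pca_first_component(np.ones((5, 5)))


class TestReceptorRegression:
    def _atlas(self, maps, sphere):
        return ReceptorAtlas(
            densities=maps, names=[f"m{i}" for i in range(maps.shape[1])], sphere=sphere
        )

    def test_single_identical_map(self, sphere100, rng):
        pc = rng.standard_normal(100)
        atlas = self._atlas(pc[:, None].copy(), sphere100)
        tbl = fs.receptor_regression(pc, atlas).set_index("transmitter")
        assert tbl.loc["m0", "beta"] == pytest.approx(1.0, abs=1e-10)
        assert tbl.loc["_r_squared", "beta"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, sphere100, rng):
        for _ in range(50):
            maps = rng.standard_normal((100, 5))
            pc = rng.standard_normal(100)
            tbl = fs.receptor_regression(pc, self._atlas(maps, sphere100))
            betas = tbl.beta.to_numpy()[:5]
            z = (maps - maps.mean(0)) / maps.std(0)
            x = np.column_stack([np.ones(100), z])
            y = (pc - pc.mean()) / pc.std()
            oracle = np.linalg.solve(x.T @ x, x.T @ y)[1:]
            assert np.allclose(betas, oracle, atol=1e-10)

    def test_orthogonal_response_gives_zero_betas(self, sphere100, rng):
        maps = rng.standard_normal((100, 4))
        pc = rng.standard_normal(100)
        x = np.column_stack([np.ones(100), maps])
        pc = pc - x @ np.linalg.lstsq(x, pc, rcond=None)[0]  # residualize
        tbl = fs.receptor_regression(pc, self._atlas(maps, sphere100))
        assert np.allclose(tbl.beta.to_numpy()[:4], 0.0, atol=1e-10)

    def test_collinear_maps_rejected(self, sphere100, rng):
        base = rng.standard_normal(100)
        maps = np.column_stack([base, base * 2.0 + 1e-12, rng.standard_normal(100)])
        with pytest.raises(ValueError, match="collinear"):
            fs.receptor_regression(rng.standard_normal(100), self._atlas(maps, sphere100))


class TestSpinNull:
    def test_rows_are_permutations_within_hemisphere(self, sphere100):
        null = fs.build_spin_null(sphere100, n_perm=20, seed=1)
        half = 50
        for row in null.permutations:
            assert np.array_equal(np.sort(row), np.arange(100))
            assert np.all(row[:half] < half)      # left stays left
            assert np.all(row[half:] >= half)     # right stays right

    @pytest.mark.parametrize("assign", [_greedy_unique_assignment, _hungarian_assignment])
    def test_identity_rotation_gives_identity(self, sphere100, assign):
        coords = sphere100.coords[:50]
        assert np.array_equal(assign(coords, coords), np.arange(50))

    def test_spins_preserve_autocorrelation(self, sphere100):
        d2 = ((sphere100.coords[:, None] - sphere100.coords[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = d2.argmin(axis=1)
        smooth = fs.gen_receptor_maps(sphere100, n_maps=1, smoothness=3, seed=14)
        m = smooth.densities[:, 0]
        orig = np.corrcoef(m, m[nn])[0, 1]
        null = fs.build_spin_null(sphere100, n_perm=100, seed=2)
        spun = np.mean([np.corrcoef(m[p], m[p][nn])[0, 1] for p in null.permutations])
        assert abs(spun - orig) / orig < 0.2

    def test_p_value_floor_and_range(self, sphere100, atlas100, rng):
        null = fs.build_spin_null(sphere100, n_perm=100, seed=3)
        tbl = fs.spin_pvalues(rng.standard_normal(100), atlas100, null)
        assert (tbl.p_spin > 0).all() and (tbl.p_spin <= 1).all()
        assert tbl.p_spin.min() >= 1.0 / 101.0

    def test_small_n_perm_warns(self, sphere100, atlas100, rng):
        null = fs.build_spin_null(sphere100, n_perm=50, seed=4)
        with pytest.warns(UserWarning, match="n_perm"):
            fs.spin_pvalues(rng.standard_normal(100), atlas100, null)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_preserves_value_multiset(self, seed):
        sph = fs.gen_sphere_parcellation(40, seed=seed)
        null = fs.build_spin_null(sph, n_perm=5, seed=seed)
        vals = np.arange(40, dtype=float)
        for p in null.permutations:
            assert np.array_equal(np.sort(vals[p]), vals)
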