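import numpy as np
import pytest
from scipy import linalg

from odieu.odor_space import (
    OdorSpace,
    cca_shared_dims,
    linear_map_predict,
    overlap,
    reduce_mds,
)


def _space(name, mat, ids=None):
    mat = np.asarray(mat, float)
    ids = ids or tuple(f"m{i}" for i in range(mat.shape[0]))
    return OdorSpace(name, tuple(ids), mat)


def brute_force_cca(x, y):
    """Canonical correlations from the generalized eigenproblem
    Sxx^-1 Sxy Syy^-1 Syx, solved directly."""
    x = x - x.mean(0)
    y = y - y.mean(0)
    sxx, syy = x.T @ x, y.T @ y
    sxy = x.T @ y
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    vals = np.linalg.eigvals(m)
    vals = np.sort(np.real(vals))[::-1]
    return np.sqrt(np.clip(vals, 0, 1))


class TestMds:
    def test_intrinsic_dim_reduces_exactly(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 12))
        _, stress = reduce_mds(_space("s", z), 3, seed=1)
        assert stress < 1e-6

    def test_simplex_needs_full_dimension(self):
        # regular 4-simplex in 4-D cannot embed in 3-D without distortion
        _, stress = reduce_mds(_space("s", np.eye(5)[:, :4]), 3, seed=1)
        assert stress > 1e-3

    def test_planar_configuration_recovered_up_to_rigid_motion(self):
        """Classical-scaling oracle: a 4-point planar set embedded in higher
        dimension reduces to 2-D with matching pairwise distances."""
        from scipy.spatial import procrustes
        from scipy.spatial.distance import pdist

        pts2d = np.array([[0, 0], [1, 0], [1, 1], [0, 2.0]])
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        ambient = np.hstack([pts2d, np.zeros((4, 3))]) @ q.T
        reduced, stress = reduce_mds(_space("s", ambient), 2, seed=0)
        assert stress < 1e-6
        np.testing.assert_allclose(pdist(reduced.coordinates), pdist(pts2d),
                                   atol=1e-6)
        _, _, disparity = procrustes(pts2d, reduced.coordinates)
        assert disparity < 1e-6

    def test_target_dim_must_shrink(self):
        with pytest.raises(ValueError):
            reduce_mds(_space("s", np.eye(4)), 4)


class TestCca:
    def test_self_comparison_sum_equals_dim(self):
        rng = np.random.default_rng(1)
        s = _space("s", rng.standard_normal((60, 4)))
        report = cca_shared_dims(s, s)
        assert report.sum_squared == pytest.approx(4.0, abs=1e-6)
        np.testing.assert_allclose(report.correlations, 1.0, atol=1e-6)

    def test_invariance_under_invertible_transforms(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((80, 3))
        y = x @ rng.standard_normal((3, 5)) + 0.5 * rng.standard_normal((80, 5))
        base = cca_shared_dims(_space("a", x), _space("b", y)).sum_squared
        t1 = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        t2 = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        trans = cca_shared_dims(_space("a", x @ t1), _space("b", y @ t2)).sum_squared
        assert trans == pytest.approx(base, abs=1e-6)

    def test_matches_generalized_eigen_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            x = rng.standard_normal((10, 2))
            y = 0.5 * x + rng.standard_normal((10, 2))
            report = cca_shared_dims(_space("a", x), _space("b", y))
            oracle = brute_force_cca(x, y)
            np.testing.assert_allclose(report.correlations, oracle, atol=1e-5)

    def test_independent_spaces_within_permutation_null(self):
        """Sum of squared correlations for independent Gaussian spaces sits
        inside the 95% band of a molecule-permutation null."""
        rng = np.random.default_rng(4)
        n, d = 200, 4
        x = rng.standard_normal((n, d))
        y = rng.standard_normal((n, d))
        ids = tuple(f"m{i}" for i in range(n))
        observed = cca_shared_dims(_space("a", x, ids), _space("b", y, ids)).sum_squared
        null = []
        for _ in range(99):
            perm = rng.permutation(n)
            null.append(cca_shared_dims(_space("a", x, ids),
                                        _space("b", y[perm], ids)).sum_squared)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= observed <= hi

    def test_small_overlap_rejected(self):
        s = _space("s", np.eye(2))
        with pytest.raises(ValueError):
            cca_shared_dims(s, s)

    def test_rank_deficient_input_handled(self):
        # n < d: PCA projection keeps min(d, n-1) components, no crash
        rng = np.random.default_rng(5)
        s1 = _space("a", rng.standard_normal((6, 10)))
        s2 = _space("b", rng.standard_normal((6, 10)))
        report = cca_shared_dims(s1, s2)
        assert report.sum_squared <= 5 + 1e-9


class TestLinearMap:
    def test_perfect_linear_link_recovered(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((100, 5))
        target = base @ rng.standard_normal((5, 5))
        r = linear_map_predict(_space("b", base), _space("t", target), seed=0)
        assert r.pearson_r > 0.999

    def test_equal_signal_noise_attenuates_to_inv_sqrt2(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal((200, 5))
            target = base + rng.standard_normal((200, 5))
            rs.append(linear_map_predict(_space("b", base), _space("t", target),
                                         seed=seed).pearson_r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - 1 / np.sqrt(2)) < 3 * se

    def test_pure_noise_gives_null_r(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            rs.append(linear_map_predict(_space("b", rng.standard_normal((100, 4))),
                                         _space("t", rng.standard_normal((100, 4))),
                                         seed=seed).pearson_r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se

    def test_asymmetry_both_directions_computed(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((80, 6))
        target = base[:, :2] @ rng.standard_normal((2, 6)) \
            + 0.3 * rng.standard_normal((80, 6))
        fwd = linear_map_predict(_space("b", base), _space("t", target), seed=1)
        rev = linear_map_predict(_space("t", target), _space("b", base), seed=1)
        assert fwd.pearson_r != pytest.approx(rev.pearson_r, abs=1e-3)

    def test_heldout_shift_does_not_leak_into_map(self):
        """Train-only centering: translating the held-out molecules leaves
        the fitted map's held-out correlation structure unchanged except for
        the shift itself (predictions change by a constant)."""
        rng = np.random.default_rng(8)
        base = rng.standard_normal((100, 4))
        target = base @ rng.standard_normal((4, 4)) + rng.standard_normal((100, 4))
        ids = tuple(f"m{i}" for i in range(100))
        r1 = linear_map_predict(_space("b", base, ids), _space("t", target, ids), seed=3)
        # shift ONLY the held-out base rows by a constant
        perm = np.random.default_rng(3).permutation(100)
        test_rows = perm[80:]
        shifted = base.copy()
        shifted[test_rows] += 7.5
        r2 = linear_map_predict(_space("b", shifted, ids), _space("t", target, ids), seed=3)
        np.testing.assert_allclose(r2.per_coordinate_r, r1.per_coordinate_r, atol=1e-9)

    def test_bad_train_fraction_rejected(self):
        s = _space("s", np.random.default_rng(0).standard_normal((20, 3)))
        with pytest.raises(ValueError):
            linear_map_predict(s, s, train_frac=1.0)


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    s = _space("latent", rng.standard_normal((10, 3)))
    s.save(tmp_path / "space.csv")
    loaded = OdorSpace.load(tmp_path / "space.csv")
    assert loaded.name == "latent"
    assert loaded.molecule_ids == s.molecule_ids
    np.testing.assert_allclose(loaded.coordinates, s.coordinates)
    assert overlap(s, loaded) == list(s.molecule_ids)
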