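import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from betaregio.containers import GridSpec
from betaregio.ordination import (
    coords_to_colors,
    nmds,
    place_by_nearest,
    procrustes_align,
    turnover_slope_map,
)
from betaregio.predictors import KM_PER_DEGREE


def unit_square_distances():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return squareform(pdist(pts))


class TestNMDS:
    def test_perfect_embedding_has_near_zero_stress(self):
        res = nmds(unit_square_distances(), n_starts=10, seed=0)
        assert res.stress < 0.01

    def test_stress_trace_non_increasing_within_each_start(self, rng):
        d = squareform(pdist(rng.random((25, 4))))
        res = nmds(d, n_starts=6, seed=3)
        for trace in res.stress_traces:
            assert (np.diff(trace) <= 1e-12).all()

    def test_returned_stress_is_min_over_starts(self, rng):
        d = squareform(pdist(rng.random((20, 5))))
        res = nmds(d, n_starts=8, seed=1)
        finals = [t[-1] for t in res.stress_traces]
        assert res.stress == pytest.approx(min(finals))
        assert res.best_start == int(np.argmin(finals))

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nmds(d, n_starts=1)

    def test_all_equal_dissimilarities_warn(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.warns(UserWarning, match="degenerate"):
            nmds(d, n_starts=1, seed=0)

    def test_stress_invariant_to_rigid_motions(self, rng):
        x = rng.random((15, 2))
        d = squareform(pdist(x))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        d_rot = squareform(pdist(x @ R + 3.0))
        r1 = nmds(d, n_starts=4, seed=2)
        r2 = nmds(d_rot, n_starts=4, seed=2)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-9)

    def test_seeded_determinism(self, rng):
        d = squareform(pdist(rng.random((12, 3))))
        r1 = nmds(d, n_starts=3, seed=7)
        r2 = nmds(d, n_starts=3, seed=7)
        np.testing.assert_array_equal(r1.coords, r2.coords)
        assert r1.stress == r2.stress

    def test_monotone_regression_matches_pava_oracle(self, rng):
        """The isotonic step inside NMDS equals a brute-force PAVA."""
        from betaregio.ordination import _isotonic_disparities

        d = rng.random(30)
        delta = rng.random(30)
        order = np.lexsort((delta, d))
        got = _isotonic_disparities(d, delta, order)

        # brute-force pooled-adjacent-violators on the sorted sequence
        y = list(delta[order])
        blocks = [[v] for v in y]
        merged = True
        while merged:
            merged = False
            for i in range(len(blocks) - 1):
                if np.mean(blocks[i]) > np.mean(blocks[i + 1]) + 1e-15:
                    blocks[i] = blocks[i] + blocks[i + 1]
                    del blocks[i + 1]
                    merged = True
                    break
        fitted = np.concatenate([[np.mean(b)] * len(b) for b in blocks])
        expected = np.empty(30)
        expected[order] = fitted
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_against_sklearn_nonmetric_mds(self, rng):
        """Independent engine: sklearn's nonmetric MDS reaches a comparable
        stress-1 on the same input."""
        from sklearn.manifold import MDS

        x = rng.random((30, 6))
        d = squareform(pdist(x))
        ours = nmds(d, n_starts=8, seed=0)
        ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  n_init=8, random_state=0, normalized_stress=True,
                  max_iter=300)
        ref.fit(d)
        assert ours.stress <= ref.stress_ + 0.05


class TestProcrustes:
    def test_identical_configurations_zero_residual(self, rng):
        x = rng.random((10, 2))
        aligned, resid = procrustes_align(x, x)
        assert resid == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(aligned, x)

    def test_rotated_copy_zero_residual(self, rng):
        x = rng.random((10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        aligned, resid = procrustes_align(x, 2.5 * x @ R + 1.0)
        assert resid == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(aligned, x, atol=1e-9)

    def test_matches_svd_oracle(self, rng):
        a = rng.random((12, 2))
        b = rng.random((12, 2))
        _, resid = procrustes_align(a, b)
        # closed-form orthogonal Procrustes with scaling, written out
        a0 = a - a.mean(0)
        b0 = b - b.mean(0)
        u, s, vt = np.linalg.svd(b0.T @ a0)
        scale = s.sum() / np.sum(b0 * b0)
        expected = np.sum(a0 * a0) - s.sum() ** 2 / np.sum(b0 * b0)
        assert resid == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            procrustes_align(rng.random((5, 2)), rng.random((6, 2)))


class TestColors:
    def test_identical_coordinates_identical_colors(self):
        coords = np.array([[0.2, 0.4], [0.2, 0.4], [0.9, 0.1]])
        colors = coords_to_colors(coords)
        np.testing.assert_array_equal(colors[0], colors[1])

    def test_corner_points_distinct(self):
        corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        colors = coords_to_colors(corners)
        assert len({tuple(c) for c in colors}) == 4

    def test_all_in_unit_cube(self, rng):
        colors = coords_to_colors(rng.normal(size=(100, 2)) * 50)
        assert (colors >= 0).all() and (colors <= 1).all()

    def test_degenerate_axis_constant_half(self):
        coords = np.array([[1.0, 0.0], [1.0, 1.0]])
        colors = coords_to_colors(coords)
        np.testing.assert_allclose(colors[:, 0], 0.5)


class TestSlopeMap:
    def _grid(self):
        return GridSpec(10, 10, 0.0, 0.1, -0.05, 0.05)  # 0.01 deg cells

    def test_constant_coordinates_zero_slope(self):
        g = self._grid()
        layers = np.full((2, 10, 10), 3.3)
        np.testing.assert_allclose(turnover_slope_map(layers, g), 0.0)

    def test_linear_ramp_closed_form(self):
        g = self._grid()
        dx_km = g.dlon * KM_PER_DEGREE * np.cos(np.deg2rad(g.lat_centers))
        ramp = np.ones((10, 1)) * np.arange(10)[None, :] * 0.05  # 0.05 per cell
        layers = np.stack([ramp, np.zeros((10, 10))])
        slope = turnover_slope_map(layers, g)
        expected = 0.05 / dx_km[:, None]
        np.testing.assert_allclose(slope[:, 1:-1], expected * np.ones((10, 8)),
                                   rtol=1e-9)

    def test_doubling_ramp_doubles_slope(self):
        g = self._grid()
        ramp = np.ones((10, 1)) * np.arange(10)[None, :]
        s1 = turnover_slope_map(np.stack([ramp, ramp]), g)
        s2 = turnover_slope_map(np.stack([2 * ramp, 2 * ramp]), g)
        np.testing.assert_allclose(s2[:, 1:-1], 2 * s1[:, 1:-1], rtol=1e-12)


def test_subsampled_nmds_approximates_full_colors(rng):
    """Large-grid strategy: subsample + nearest-neighbor placement keeps the
    color structure of the full embedding (rank correlation > 0.9)."""
    from scipy.stats import spearmanr

    # three blobs in feature space with distances driven by the features
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 4.0]])
    feats = np.vstack([c + 0.4 * rng.normal(size=(60, 2)) for c in centers])
    d = squareform(pdist(feats))
    d = d / d.max()
    full = nmds(d, n_starts=4, seed=0, max_iter=150)
    sub = np.sort(rng.choice(len(feats), size=90, replace=False))
    rest = np.setdiff1d(np.arange(len(feats)), sub)
    part = nmds(d[np.ix_(sub, sub)], n_starts=4, seed=0, max_iter=150)
    coords = np.empty((len(feats), 2))
    coords[sub] = part.coords
    coords[rest] = place_by_nearest(part.coords, feats[sub], feats[rest])
    aligned, _ = procrustes_align(full.coords, coords)
    col_full = coords_to_colors(full.coords)
    col_sub = coords_to_colors(aligned)
    for k in range(3):
        rho = spearmanr(col_full[:, k], col_sub[:, k]).statistic
        assert rho > 0.9
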