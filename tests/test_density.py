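import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sptraj.density import (DensityField, build_weight_map, default_bandwidth,
                            detect_low_confidence, estimate_density,
                            fuse_distances, map_density_to_alpha,
                            normalize_density)
from sptraj.graph import build_alpha_adjacency, estimate_radius_delta


class TestDensityEstimate:
    def test_single_cell_closed_form(self):
        b = 0.7
        f = estimate_density(np.array([[3.0, 4.0]]), bandwidth=b)
        expected = np.exp(1.0 / (b * np.sqrt(2 * np.pi)))
        assert f.rho_hat[0] == pytest.approx(expected)

    def test_two_far_points_self_term_only(self):
        b = 0.1
        f = estimate_density(np.array([[0.0, 0], [100.0, 0]]), bandwidth=b)
        # K(1000) ~ 0: only the self term K(0) = 1/sqrt(2 pi) survives
        expected = np.exp(1.0 / (2 * b) / np.sqrt(2 * np.pi))
        np.testing.assert_allclose(f.rho_hat, expected, rtol=1e-12)

    def test_cluster_denser_than_outlier(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 0.3, (20, 2)), [[50.0, 50.0]]])
        f = estimate_density(coords, bandwidth=1.0)
        assert (f.rho_hat[:20] > f.rho_hat[20]).all()

    def test_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 5, (15, 2))
        b = 0.8
        f = estimate_density(coords, bandwidth=b)
        n = len(coords)
        for i in (0, 7, 14):
            s = sum(np.exp(-0.5 * (np.linalg.norm(coords[i] - coords[j]) / b) ** 2)
                    / np.sqrt(2 * np.pi) for j in range(n))
            assert f.rho_hat[i] == pytest.approx(np.exp(s / (n * b)))

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            estimate_density(np.zeros((3, 2)), bandwidth=-1.0)

    def test_default_bandwidth_positive(self):
        rng = np.random.default_rng(2)
        assert default_bandwidth(rng.uniform(0, 5, (30, 2))) > 0


class TestNormalize:
    def test_constant_field_maps_to_zero(self):
        f = normalize_density(DensityField(np.full(5, 2.0), 1.0))
        assert (f.rho == 0).all()

    def test_linear_map_values(self):
        f = normalize_density(DensityField(np.array([1.0, 2.0, 3.0]), 1.0))
        np.testing.assert_allclose(f.rho, [0, 0.5, 1.0], atol=1e-9)

    def test_order_preserved(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(1, 5, 40)
        f = normalize_density(DensityField(r, 1.0))
        np.testing.assert_array_equal(np.argsort(f.rho), np.argsort(r))


class TestAlphaMap:
    def test_endpoints(self):
        assert map_density_to_alpha(np.array([1.0]), 0.2, 0.8)[0] == \
            pytest.approx(0.2)
        assert map_density_to_alpha(np.array([0.0]), 0.2, 0.8)[0] == \
            pytest.approx(0.8)

    def test_midpoint(self):
        assert map_density_to_alpha(np.array([0.5]), 0.2, 0.8)[0] == \
            pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.floats(0, 0.5), st.floats(0.5, 1))
    def test_monotone_and_bounded(self, rho, amin, amax):
        rho = np.array(rho)
        a = map_density_to_alpha(rho, amin, amax)
        assert ((a >= amin - 1e-12) & (a <= amax + 1e-12)).all()
        order = np.argsort(rho)
        assert (np.diff(a[order]) <= 1e-12).all()

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            map_density_to_alpha(np.array([0.5]), 0.9, 0.1)


@pytest.fixture(scope="module")
def grid_graph():
    xs, ys = np.meshgrid(np.arange(7.0), np.arange(7.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    coords += np.random.default_rng(0).normal(0, 1e-3, coords.shape)
    g = build_alpha_adjacency(coords, estimate_radius_delta(coords))
    return coords, g


class TestLowConfidence:
    def test_interior_not_flagged_corner_flagged(self, grid_graph):
        coords, g = grid_graph
        mask = detect_low_confidence(coords, g)
        center = 3 * 7 + 3
        corner = int(np.argmin(coords.sum(axis=1)))
        assert not mask[center]
        assert mask[corner]

    def test_remote_node_flagged(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.uniform(0, 5, (40, 2)), [[60.0, 60.0]]])
        g = build_alpha_adjacency(coords, delta=200.0)  # keeps long edges
        mask = detect_low_confidence(coords, g, hole_factor=3.0)
        assert mask[40]
        # brute-force criterion check for the remote node
        nb = g.neighbors(40)
        med = np.median([np.linalg.norm(coords[i] - coords[j])
                         for i, j in g.edge_list()])
        assert np.linalg.norm(coords[nb] - coords[40], axis=1).mean() > 3 * med


class TestFusion:
    def _random(self, seed, n=20):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, 6)), rng.uniform(0, 10, (n, 2))

    def test_alpha_one_gives_spatial(self):
        Z, coords = self._random(0)
        fc = fuse_distances(Z, coords, np.ones(len(Z)))
        np.testing.assert_array_equal(fc.M, fc.ds)

    def test_alpha_zero_gives_embedding(self):
        Z, coords = self._random(1)
        fc = fuse_distances(Z, coords, np.zeros(len(Z)))
        np.testing.assert_array_equal(fc.M, fc.dg)

    def test_hand_computed_three_cells(self):
        Z = np.array([[0.0], [1.0], [3.0]])
        coords = np.array([[0.0, 0], [4.0, 0], [4.0, 3.0]])
        fc = fuse_distances(Z, coords, np.full(3, 0.5))
        # spatial distances 4,5,3 -> /5; embedding 1,3,2 -> /3
        np.testing.assert_allclose(fc.ds[0, 1], 4 / 5)
        np.testing.assert_allclose(fc.dg[0, 2], 1.0)
        np.testing.assert_allclose(fc.M[0, 1], 0.5 * (4 / 5) + 0.5 * (1 / 3))
        np.testing.assert_allclose(fc.M[1, 2], 0.5 * (3 / 5) + 0.5 * (2 / 3))

    @pytest.mark.parametrize("seed", range(3))
    def test_convexity_bounds(self, seed):
        Z, coords = self._random(seed, n=30)
        alpha = np.random.default_rng(seed + 100).uniform(0, 1, 30)
        fc = fuse_distances(Z, coords, alpha)
        off = ~np.eye(30, dtype=bool)
        lo = np.minimum(fc.ds, fc.dg)
        hi = np.maximum(fc.ds, fc.dg)
        assert (fc.M[off] >= lo[off] - 1e-12).all()
        assert (fc.M[off] <= hi[off] + 1e-12).all()

    def test_degenerate_coords_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fuse_distances(np.random.default_rng(0).normal(size=(4, 2)),
                           np.zeros((4, 2)), np.full(4, 0.5))

    def test_asymmetry_from_row_alpha(self):
        Z, coords = self._random(2)
        alpha = np.linspace(0, 1, len(Z))
        fc = fuse_distances(Z, coords, alpha)
        assert not np.allclose(fc.M, fc.M.T)


class TestWeightMap:
    def test_protected_cells_carry_alpha_prot(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (60, 2))
        g = build_alpha_adjacency(coords, estimate_radius_delta(coords))
        wm = build_weight_map(coords, g, alpha_min=0.2, alpha_max=0.8,
                              alpha_prot=0.37)
        assert wm.protected.any()
        assert (wm.alpha_tilde[wm.protected] == 0.37).all()
        unprot = ~wm.protected
        np.testing.assert_array_equal(wm.alpha_tilde[unprot], wm.alpha[unprot])

    def test_non_adaptive_constant(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (40, 2))
        g = build_alpha_adjacency(coords, estimate_radius_delta(coords))
        wm = build_weight_map(coords, g, alpha_min=0.2, alpha_max=0.8,
                              adaptive=False)
        assert (wm.alpha_tilde == 0.5).all()
        assert not wm.protected.any()
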