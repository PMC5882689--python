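"""Distance-to-coast, conductance, and least-cost-path extraction."""

import numpy as np
import networkx as nx
import pytest

from oceanssf.cost_path import (
    conductance_surface,
    distance_to_coast,
    least_cost_path,
)
from oceanssf.geodesy import gc_distance
from oceanssf.raster import RasterGrid, bilinear_interpolate
import oceanssf as o

KM_PER_DEG = 111.19492664455873


def brute_force_min_cost(cond: RasterGrid, s: tuple, e: tuple) -> float:
    """Exhaustive DFS over all simple 8-connected paths, pruned only when the
    partial cost already exceeds the best complete path (exact optimum)."""
    nr, nc = cond.n_rows, cond.n_cols
    lats, lons = cond.lat_centers(), cond.lon_centers()
    c = cond.values
    best = [np.inf]

    def edge(a, b):
        return gc_distance(lats[a[0]], lons[a[1]], lats[b[0]], lons[b[1]]) / (
            0.5 * (c[a] + c[b])
        )

    def dfs(node, cost, visited):
        if cost >= best[0]:
            return
        if node == e:
            best[0] = cost
            return
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (node[0] + dr, node[1] + dc)
                if 0 <= nb[0] < nr and 0 <= nb[1] < nc and nb not in visited:
                    visited.add(nb)
                    dfs(nb, cost + edge(node, nb), visited)
                    visited.remove(nb)

    dfs(s, 0.0, {s})
    return best[0]


def random_cond(rng, nr, nc):
    return RasterGrid(0.0, 0.0, 0.5, rng.uniform(0.05, 2.0, size=(nr, nc)))


class TestDistanceToCoast:
    def test_coastal_cells_are_zero(self):
        mask = RasterGrid(0.0, 0.0, 1.0, np.array([[1.0, 0.0, 0.0, 0.0]]))
        d = distance_to_coast(mask)
        assert d.values[0, 0] == 0.0  # land with sea neighbor
        assert d.values[0, 1] == 0.0  # sea with land neighbor

    def test_equator_row_distance_closed_form(self):
        # land at col 0; coastal set = {col0, col1}; col 4 is 3 cells from col 1
        mask = RasterGrid(0.0, 0.0, 1.0, np.array([[1.0, 0, 0, 0, 0, 0, 0]]))
        d = distance_to_coast(mask)
        assert d.values[0, 4] == pytest.approx(3 * KM_PER_DEG, rel=1e-9)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        mask = RasterGrid(-2.0, 0.0, 1.0, (rng.random((5, 9)) > 0.7).astype(float))
        if mask.values.sum() in (0, mask.values.size):
            mask.values[0, 0] = 1 - mask.values[0, 0]
        d = distance_to_coast(mask)
        mirrored = mask.copy_with(mask.values[:, ::-1])
        dm = distance_to_coast(mirrored)
        np.testing.assert_allclose(dm.values, d.values[:, ::-1], rtol=1e-9)

    def test_all_land_or_all_sea_rejected(self):
        for fill in (0.0, 1.0):
            with pytest.raises(ValueError):
                distance_to_coast(RasterGrid(0.0, 0.0, 1.0, np.full((3, 3), fill)))


class TestConductance:
    def test_inverse_values(self):
        d = RasterGrid(0.0, 0.0, 1.0, np.array([[0.0, 9.0]]))
        c = conductance_surface(d, epsilon=1.0)
        np.testing.assert_allclose(c.values, [[1.0, 0.1]])

    def test_monotone_decreasing_in_distance(self):
        d = RasterGrid(0.0, 0.0, 1.0, np.arange(12.0).reshape(3, 4))
        c = conductance_surface(d, epsilon=2.0)
        flat = c.values.ravel()
        assert np.all(np.diff(flat) < 0)

    def test_nonpositive_epsilon_rejected(self):
        d = RasterGrid(0.0, 0.0, 1.0, np.ones((2, 2)))
        with pytest.raises(ValueError):
            conductance_surface(d, epsilon=0.0)

    def test_default_epsilon_is_cell_scale(self):
        d = RasterGrid(0.0, 0.0, 1.0, np.zeros((3, 3)))
        c = conductance_surface(d)
        # 1/epsilon with epsilon ~ one cell diagonal (~157 km at 1 deg, equator)
        assert c.values[0, 0] == pytest.approx(1.0 / (KM_PER_DEG * np.sqrt(2)), rel=1e-2)


class TestLeastCostPath:
    def test_uniform_conductance_straight_row(self):
        cond = RasterGrid(0.0, 0.0, 1.0, np.full((3, 5), 2.0))
        res = least_cost_path(cond, 1.0, 0.0, 1.0, 4.0)
        np.testing.assert_allclose(res.path_lat, np.full(5, 1.0))
        np.testing.assert_allclose(res.path_lon, np.arange(5.0))
        seg = gc_distance(1.0, 0.0, 1.0, 1.0)
        assert res.total_cost == pytest.approx(4 * seg / 2.0, rel=1e-9)

    def test_wall_with_gap_forces_detour(self):
        cond = np.full((5, 5), 1.0)
        cond[:, 2] = 1e-12  # near-impassable wall ...
        cond[2, 2] = 1.0  # ... with a gap in the middle row
        grid = RasterGrid(0.0, 0.0, 0.5, cond)
        res = least_cost_path(grid, 0.0, 0.0, 0.0, 2.0)
        path = set(zip(res.path_lat, res.path_lon))
        assert (1.0, 1.0) in path  # passes through the gap cell center
        assert res.total_cost == pytest.approx(
            brute_force_min_cost(grid, (0, 0), (0, 4)), rel=1e-9
        )

    def test_matches_enumeration_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            nr, nc = rng.integers(2, 5, size=2)
            cond = random_cond(rng, nr, nc)
            s = (int(rng.integers(nr)), int(rng.integers(nc)))
            e = (int(rng.integers(nr)), int(rng.integers(nc)))
            if s == e:
                continue
            res = least_cost_path(cond, *cond.cell_center(*s), *cond.cell_center(*e))
            assert res.total_cost == pytest.approx(
                brute_force_min_cost(cond, s, e), rel=1e-9
            )

    def test_matches_networkx_on_5x5(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cond = random_cond(rng, 5, 5)
            G = nx.Graph()
            for r in range(5):
                for c in range(5):
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = r + dr, c + dc
                            if (dr, dc) != (0, 0) and 0 <= r2 < 5 and 0 <= c2 < 5:
                                lat1, lon1 = cond.cell_center(r, c)
                                lat2, lon2 = cond.cell_center(r2, c2)
                                w = gc_distance(lat1, lon1, lat2, lon2) / (
                                    0.5 * (cond.values[r, c] + cond.values[r2, c2])
                                )
                                G.add_edge((r, c), (r2, c2), weight=w)
            expect = nx.shortest_path_length(G, (0, 0), (4, 4), weight="weight")
            res = least_cost_path(cond, *cond.cell_center(0, 0), *cond.cell_center(4, 4))
            assert res.total_cost == pytest.approx(expect, rel=1e-9)

    def test_scale_invariance_and_symmetry(self):
        rng = np.random.default_rng(1)
        cond = random_cond(rng, 4, 6)
        a = least_cost_path(cond, *cond.cell_center(0, 0), *cond.cell_center(3, 5))
        doubled = cond.copy_with(cond.values * 2.0)
        b = least_cost_path(doubled, *cond.cell_center(0, 0), *cond.cell_center(3, 5))
        assert b.total_cost == pytest.approx(a.total_cost / 2.0, rel=1e-12)
        np.testing.assert_array_equal(a.path_lat, b.path_lat)
        rev = least_cost_path(cond, *cond.cell_center(3, 5), *cond.cell_center(0, 0))
        assert rev.total_cost == pytest.approx(a.total_cost, rel=1e-12)

    def test_snapped_identical_endpoints_give_trivial_path(self):
        cond = RasterGrid(0.0, 0.0, 1.0, np.ones((3, 3)))
        res = least_cost_path(cond, 1.1, 1.2, 0.9, 0.8)
        assert len(res) == 1 and res.total_cost == 0.0

    def test_barrier_unreachable_raises(self):
        cond = np.ones((3, 3))
        cond[:, 1] = 0.0  # zero conductance: no edges cross
        with pytest.raises(ValueError, match="unreachable"):
            least_cost_path(RasterGrid(0.0, 0.0, 1.0, cond), 1.0, 0.0, 1.0, 2.0)


def test_archipelago_lcp_hugs_coast(world):
    """The optimal route follows the island chain, unlike the straight line."""
    cfg, _mask, dcoast, _wind = world
    cond = conductance_surface(dcoast)
    start = (cfg.start_lat, cfg.start_lon)
    end = (cfg.grid_lat_min + 2.0, (cfg.grid_lon_min + cfg.grid_lon_max) / 2 - 1.5)
    res = o.least_cost_path(cond, *start, *end)
    lcp_mean = np.mean(bilinear_interpolate(dcoast, res.path_lat, res.path_lon))
    t = np.linspace(0.0, 1.0, 200)
    line_lat = start[0] + t * (end[0] - start[0])
    line_lon = start[1] + t * (end[1] - start[1])
    line_mean = np.mean(bilinear_interpolate(dcoast, line_lat, line_lon))
    assert lcp_mean < line_mean
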