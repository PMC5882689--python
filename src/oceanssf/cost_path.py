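"""Least-cost route through an island chain.

A migration route that minimizes over-water flight is modelled as the
least-cost path over a conductance surface equal to the inverse of
distance to coast: travel is cheap along coastlines and over islands,
expensive over open ocean.  The grid is treated as an 8-connected graph;
each edge costs great-circle length divided by the mean conductance of
its two cells, and the optimum is extracted with Dijkstra's algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .geodesy import EARTH_RADIUS_KM, gc_distance
from .raster import RasterGrid

_KING = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
_KNIGHT = [
    (dr, dc)
    for dr in (-2, -1, 1, 2)
    for dc in (-2, -1, 1, 2)
    if {abs(dr), abs(dc)} == {1, 2}
]
NEIGHBORHOODS = {
    4: [(-1, 0), (1, 0), (0, -1), (0, 1)],
    8: _KING,
    16: _KING + _KNIGHT,
}


@dataclass
class LCPResult:
    """An ordered least-cost route over cell centers and its total cost."""

    path_lat: np.ndarray
    path_lon: np.ndarray
    total_cost: float
    cum_cost: np.ndarray

    def __len__(self) -> int:
        return len(self.path_lat)


def _unit_sphere_xyz(lat_deg: np.ndarray, lon_deg: np.ndarray) -> np.ndarray:
    phi = np.radians(lat_deg)
    lam = np.radians(lon_deg)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def coastal_cells(mask: RasterGrid) -> np.ndarray:
    """Boolean grid of coastal cells: land with a sea 4-neighbor or sea with a land 4-neighbor."""
    land = mask.values > 0.5
    if land.all() or not land.any():
        raise ValueError("mask must contain both land and sea cells")
    diff = np.zeros_like(land, dtype=bool)
    diff[:-1, :] |= land[:-1, :] != land[1:, :]
    diff[1:, :] |= land[1:, :] != land[:-1, :]
    diff[:, :-1] |= land[:, :-1] != land[:, 1:]
    diff[:, 1:] |= land[:, 1:] != land[:, :-1]
    return diff


def distance_to_coast(mask: RasterGrid) -> RasterGrid:
    """Great-circle distance (km) from every cell center to the nearest coastal cell center.

    Coastal cells score 0.  Exact nearest-neighbour search via a k-d tree
    on the unit-sphere embedding (chord distance is monotone in
    great-circle distance, so the nearest chord neighbour is the nearest
    geodesic neighbour).
    """
    coast = coastal_cells(mask)
    lats = mask.lat_centers()
    lons = mask.lon_centers()
    glon, glat = np.meshgrid(lons, lats)
    xyz = _unit_sphere_xyz(glat.ravel(), glon.ravel())
    tree = cKDTree(xyz[coast.ravel()])
    chord, _ = tree.query(xyz, k=1)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    d = d.reshape(mask.values.shape)
    d[coast] = 0.0
    return mask.copy_with(d)


def conductance_surface(dcoast: RasterGrid, epsilon: float | None = None) -> RasterGrid:
    """Conductance = 1 / (distance-to-coast + epsilon).

    The inverse layer is undefined at d = 0, so a positive floor epsilon
    is required; the default is one cell diagonal in km at the grid's
    central latitude, keeping coastal conductance finite at a
    resolution-consistent scale.
    """
    if epsilon is None:
        mid_lat = dcoast.origin_lat + (dcoast.n_rows - 1) * dcoast.res / 2.0
        dlat = dcoast.res * np.pi / 180.0 * EARTH_RADIUS_KM
        dlon = dlat * np.cos(np.radians(mid_lat))
        epsilon = float(np.hypot(dlat, dlon))
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = dcoast.values
    if np.any(d < 0):
        raise ValueError("distance-to-coast values must be non-negative")
    return dcoast.copy_with(1.0 / (d + epsilon))


def _build_graph(cond: RasterGrid, neighbors: int):
    nr, nc = cond.n_rows, cond.n_cols
    c = cond.values.ravel()
    ok = (c > 0) & (c != cond.nodata)
    lats = np.repeat(cond.lat_centers(), nc)
    lons = np.tile(cond.lon_centers(), nr)
    rows_i, cols_i, costs = [], [], []
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    for dr, dc in NEIGHBORHOODS[neighbors]:
        if dr < 0 or (dr == 0 and dc < 0):
            continue  # each undirected edge once
        r2 = rr + dr
        c2 = cc + dc
        valid = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
        i = np.flatnonzero(valid)
        j = r2[valid] * nc + c2[valid]
        good = ok[i] & ok[j]
        i, j = i[good], j[good]
        if len(i) == 0:
            continue
        length = gc_distance(lats[i], lons[i], lats[j], lons[j])
        mean_c = 0.5 * (c[i] + c[j])
        rows_i.append(i)
        cols_i.append(j)
        costs.append(np.asarray(length) / mean_c)
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_i)
    w = np.concatenate(costs)
    n = nr * nc
    return coo_matrix((w, (i, j)), shape=(n, n)).tocsr()


def least_cost_path(
    cond: RasterGrid,
    start_lat: float,
    start_lon: float,
    end_lat: float,
    end_lon: float,
    neighbors: int = 8,
) -> LCPResult:
    """Minimum-cost route between two points over the conductance graph.

    Start/end snap to the nearest cell centers.  Edge cost between
    neighbouring cells i, j is gc_distance(center_i, center_j) divided by
    the arithmetic mean of their conductances; cells with non-positive or
    nodata conductance carry no edges.
    """
    if neighbors not in NEIGHBORHOODS:
        raise ValueError(f"neighbors must be one of {sorted(NEIGHBORHOODS)}")
    r0, c0 = cond.nearest_cell(start_lat, start_lon)
    r1, c1 = cond.nearest_cell(end_lat, end_lon)
    nc = cond.n_cols
    s, e = r0 * nc + c0, r1 * nc + c1
    lats = np.repeat(cond.lat_centers(), nc)
    lons = np.tile(cond.lon_centers(), cond.n_rows)
    if s == e:
        return LCPResult(
            np.array([lats[s]]), np.array([lons[s]]), 0.0, np.array([0.0])
        )
    graph = _build_graph(cond, neighbors)
    dist, pred = dijkstra(
        graph, directed=False, indices=s, return_predecessors=True
    )
    if not np.isfinite(dist[e]):
        raise ValueError("end point unreachable from start (conductance barrier)")
    node_path = [e]
    while node_path[-1] != s:
        node_path.append(int(pred[node_path[-1]]))
    node_path.reverse()
    idx = np.array(node_path)
    plat, plon = lats[idx], lons[idx]
    seg = np.asarray(gc_distance(plat[:-1], plon[:-1], plat[1:], plon[1:]))
    cond_vals = cond.values.ravel()[idx]
    seg_cost = seg / (0.5 * (cond_vals[:-1] + cond_vals[1:]))
    cum = np.concatenate([[0.0], np.cumsum(seg_cost)])
    return LCPResult(plat, plon, float(dist[e]), cum)
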