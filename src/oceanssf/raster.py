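"""Regular lat/lon rasters and time-indexed grid stacks.

``RasterGrid`` stores values row 0 = southernmost row (origin is the
lower-left *cell center*), square cells of ``res`` degrees.  Files are
plain ESRI ASCII grids (.asc), which store rows north-to-south; the
reader/writer flips accordingly.  A sidecar ``.prj.txt`` notes the CRS
(geographic WGS84-like sphere) for downstream GIS users.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RasterGrid:
    """Regular geographic grid of values.

    origin_lat/origin_lon: center of the lower-left (south-west) cell.
    res: cell size in degrees (square cells).
    values: (n_rows, n_cols) array, row 0 = southernmost.
    """

    origin_lat: float
    origin_lon: float
    res: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.res <= 0:
            raise ValueError("res must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row, col):
        """(lat, lon) of the center of cell (row, col)."""
        return (
            self.origin_lat + np.asarray(row) * self.res,
            self.origin_lon + np.asarray(col) * self.res,
        )

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat + np.arange(self.n_rows) * self.res

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + np.arange(self.n_cols) * self.res

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell whose center is nearest the point (grid metric)."""
        r = int(round((lat - self.origin_lat) / self.res))
        c = int(round((lon - self.origin_lon) / self.res))
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError(f"point ({lat}, {lon}) outside grid extent")
        return r, c

    def contains(self, lat, lon) -> np.ndarray:
        """True where the point lies inside the outer cell-center rectangle."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.origin_lat)
            & (lat <= self.origin_lat + (self.n_rows - 1) * self.res)
            & (lon >= self.origin_lon)
            & (lon <= self.origin_lon + (self.n_cols - 1) * self.res)
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_lat, self.origin_lon, self.res, values, self.nodata)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_lat - other.origin_lat) < 1e-9
            and abs(self.origin_lon - other.origin_lon) < 1e-9
            and abs(self.res - other.res) < 1e-12
        )


def bilinear_interpolate(grid: RasterGrid, lat, lon):
    """Bilinear interpolation among the four surrounding cell centers.

    Exact at cell centers and for any function affine in (lat, lon).
    Points outside the outer cell-center rectangle raise ValueError
    naming the offending point; if any of the four surrounding nodes is
    nodata the result is nodata.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    scalar = lat.ndim == 0 and lon.ndim == 0
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
    inside = grid.contains(lat, lon)
    if not np.all(inside):
        i = int(np.argmin(inside))
        raise ValueError(f"point ({lat[i]}, {lon[i]}) outside grid interpolation domain")
    fr = (lat - grid.origin_lat) / grid.res
    fc = (lon - grid.origin_lon) / grid.res
    r0 = np.clip(np.floor(fr).astype(int), 0, grid.n_rows - 2) if grid.n_rows > 1 else np.zeros_like(fr, dtype=int)
    c0 = np.clip(np.floor(fc).astype(int), 0, grid.n_cols - 2) if grid.n_cols > 1 else np.zeros_like(fc, dtype=int)
    tr = fr - r0
    tc = fc - c0
    v = grid.values
    r1 = np.minimum(r0 + 1, grid.n_rows - 1)
    c1 = np.minimum(c0 + 1, grid.n_cols - 1)
    q00, q01, q10, q11 = v[r0, c0], v[r0, c1], v[r1, c0], v[r1, c1]
    out = (
        q00 * (1 - tr) * (1 - tc)
        + q01 * (1 - tr) * tc
        + q10 * tr * (1 - tc)
        + q11 * tr * tc
    )
    bad = (q00 == grid.nodata) | (q01 == grid.nodata) | (q10 == grid.nodata) | (q11 == grid.nodata)
    out = np.where(bad, grid.nodata, out)
    return float(out[0]) if scalar else out


def write_ascii_grid(grid: RasterGrid, path: str | Path, crs_note: bool = True) -> None:
    """Write an ESRI ASCII grid plus a sidecar CRS note."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon - grid.res / 2.0:.17g}\n")
        fh.write(f"yllcorner {grid.origin_lat - grid.res / 2.0:.17g}\n")
        fh.write(f"cellsize {grid.res:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        np.savetxt(fh, grid.values[::-1], fmt="%.17g")
    if crs_note:
        Path(str(path) + ".prj.txt").write_text(
            "geographic lat/lon degrees, spherical Earth R=6371 km\n"
        )


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    res = header["cellsize"]
    grid = RasterGrid(
        origin_lat=header["yllcorner"] + res / 2.0,
        origin_lon=header["xllcorner"] + res / 2.0,
        res=res,
        values=values[::-1],
        nodata=header.get("nodata_value", -9999.0),
    )
    if grid.n_rows != int(header["nrows"]) or grid.n_cols != int(header["ncols"]):
        raise ValueError(f"{path}: data shape disagrees with header")
    return grid


@dataclass
class GridSeries:
    """A time-indexed stack of rasters sharing one geometry."""

    times: list[pd.Timestamp]
    grids: list[RasterGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.grids):
            raise ValueError("times and grids length mismatch")
        if len(self.times) == 0:
            raise ValueError("GridSeries needs at least one layer")
        self.times = [pd.Timestamp(t) for t in self.times]
        order = np.argsort(np.array([t.value for t in self.times]))
        self.times = [self.times[i] for i in order]
        self.grids = [self.grids[i] for i in order]
        g0 = self.grids[0]
        for g in self.grids[1:]:
            if not g.same_geometry(g0):
                raise ValueError("all grids in a series must share geometry")

    def nearest_index(self, t) -> int:
        t = pd.Timestamp(t)
        deltas = np.array([abs((t - ti).value) for ti in self.times])
        return int(np.argmin(deltas))

    def nearest(self, t) -> RasterGrid:
        return self.grids[self.nearest_index(t)]


@dataclass
class WindField:
    """Paired eastward (u) and northward (v) wind stacks at one pressure level."""

    u: GridSeries
    v: GridSeries

    def __post_init__(self) -> None:
        if self.u.times != self.v.times:
            raise ValueError("u and v series must share timestamps")

    @property
    def times(self) -> list[pd.Timestamp]:
        return self.u.times

    def nearest(self, t) -> tuple[RasterGrid, RasterGrid]:
        i = self.u.nearest_index(t)
        return self.u.grids[i], self.v.grids[i]


_TS_FMT = "%Y%m%dT%H%M%S"


def write_wind_field(wind: WindField, out_dir: str | Path) -> list[Path]:
    """One u_/v_<ISO-stamp>.asc pair per timestamp."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t, gu, gv in zip(wind.times, wind.u.grids, wind.v.grids):
        stamp = t.strftime(_TS_FMT)
        for prefix, g in (("u", gu), ("v", gv)):
            p = out_dir / f"{prefix}_{stamp}.asc"
            write_ascii_grid(g, p, crs_note=False)
            written.append(p)
    return written


def read_wind_field(wind_dir: str | Path) -> WindField:
    wind_dir = Path(wind_dir)
    pat = re.compile(r"^([uv])_(\d{8}T\d{6})\.asc$")
    stacks: dict[str, dict[pd.Timestamp, RasterGrid]] = {"u": {}, "v": {}}
    for p in sorted(wind_dir.iterdir()):
        m = pat.match(p.name)
        if m:
            comp, stamp = m.groups()
            stacks[comp][pd.Timestamp(stamp)] = read_ascii_grid(p)
    if not stacks["u"] or set(stacks["u"]) != set(stacks["v"]):
        raise ValueError(f"{wind_dir}: incomplete u/v wind layer pairs")
    times = sorted(stacks["u"])
    return WindField(
        u=GridSeries(times, [stacks["u"][t] for t in times]),
        v=GridSeries(times, [stacks["v"][t] for t in times]),
    )
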