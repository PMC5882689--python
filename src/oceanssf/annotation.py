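"""Environmental annotation of steps and covariate preparation.

Each step is annotated at its *end* point (the location whose selection
the model explains; start/midpoint evaluation are options), using
bilinear interpolation in the static distance-to-coast raster and in the
wind layer nearest in time to the stratum's start time (wind layers are
coarse in time, e.g. 6-hourly, and no temporal interpolation is done).

The wind vector (u eastward, v northward, m/s) is decomposed along the
step heading into *wind support* (signed projection onto the heading;
positive = tailwind) and *crosswind* (perpendicular component; the model
covariate is its magnitude).  Decomposition is a rotation, so
support**2 + signed_crosswind**2 == u**2 + v**2.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .raster import GridSeries, RasterGrid, WindField, bilinear_interpolate

__all__ = [
    "bilinear_interpolate",
    "wind_decompose",
    "annotate_steps",
    "scale_covariates",
    "unscale_covariates",
    "collinearity_screen",
]


def wind_decompose(u, v, heading_deg):
    """(wind_support, signed_crosswind) of wind (u, v) along a heading.

    heading in degrees clockwise from north.  Wind support is the wind
    component along the heading (negative = headwind); signed crosswind
    is the component perpendicular to it (positive = wind from the
    left of track, pushing rightward).
    """
    th = np.radians(np.asarray(heading_deg, dtype=float))
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    support = u * np.sin(th) + v * np.cos(th)
    cross = u * np.cos(th) - v * np.sin(th)
    if support.shape:
        return support, cross
    return float(support), float(cross)


def _eval_points(steps: pd.DataFrame, at: str) -> tuple[np.ndarray, np.ndarray]:
    if at == "end":
        return steps["lat2"].to_numpy(float), steps["lon2"].to_numpy(float)
    if at == "start":
        return steps["lat1"].to_numpy(float), steps["lon1"].to_numpy(float)
    if at == "mid":  # chord midpoint; adequate at these step lengths
        return (
            0.5 * (steps["lat1"].to_numpy(float) + steps["lat2"].to_numpy(float)),
            0.5 * (steps["lon1"].to_numpy(float) + steps["lon2"].to_numpy(float)),
        )
    raise ValueError(f"unknown evaluation point {at!r} (use end/start/mid)")


def annotate_steps(
    steps: pd.DataFrame,
    dcoast: RasterGrid,
    wind: WindField,
    aux: Mapping[str, RasterGrid | GridSeries] | None = None,
    at: str = "end",
    signed_crosswind: bool = False,
) -> pd.DataFrame:
    """Attach covariates to every step row.

    Adds ``dist_coast_km, u_ms, v_ms, wind_support_ms, crosswind_ms``
    plus one column per ``aux`` field (static rasters or time-indexed
    series, matched like the wind).  ``crosswind_ms`` is the magnitude
    unless ``signed_crosswind``; the signed value is always kept as
    ``crosswind_signed_ms``.
    """
    out = steps.copy().reset_index(drop=True)
    lat, lon = _eval_points(out, at)
    try:
        out["dist_coast_km"] = bilinear_interpolate(dcoast, lat, lon)
    except ValueError as err:
        bad = ~dcoast.contains(lat, lon)
        ids = sorted(out.loc[bad, "stratum_id"].unique().tolist())
        raise ValueError(f"step endpoints outside raster coverage in strata {ids}") from err

    t_start = pd.to_datetime(out["t_start"])
    layer_idx = np.array([wind.u.nearest_index(t) for t in t_start])
    u = np.empty(len(out))
    v = np.empty(len(out))
    for k in np.unique(layer_idx):
        sel = layer_idx == k
        u[sel] = bilinear_interpolate(wind.u.grids[k], lat[sel], lon[sel])
        v[sel] = bilinear_interpolate(wind.v.grids[k], lat[sel], lon[sel])
    out["u_ms"] = u
    out["v_ms"] = v
    support, cross = wind_decompose(u, v, out["heading_deg"].to_numpy(float))
    out["wind_support_ms"] = support
    out["crosswind_signed_ms"] = cross
    out["crosswind_ms"] = cross if signed_crosswind else np.abs(cross)

    for name, grids in (aux or {}).items():
        vals = np.empty(len(out))
        if isinstance(grids, RasterGrid):
            vals[:] = bilinear_interpolate(grids, lat, lon)
        else:
            aidx = np.array([grids.nearest_index(t) for t in t_start])
            for k in np.unique(aidx):
                sel = aidx == k
                vals[sel] = bilinear_interpolate(grids.grids[k], lat[sel], lon[sel])
        out[name] = vals
    return out


def scale_covariates(
    steps: pd.DataFrame,
    variables: list[str],
    scaling: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score covariates over all rows (cases and alternatives pooled).

    Appends ``<var>_scaled`` columns and returns (table, scaling) where
    scaling holds the mean and SD (ddof=1) per variable for
    back-transformation.  Pass an existing ``scaling`` table to apply a
    fixed transform (e.g. training-fold moments to a held-out fold, or a
    simulation's declared truth scale).
    """
    out = steps.copy()
    if scaling is None:
        rows = []
        for var in variables:
            x = out[var].to_numpy(float)
            if np.unique(x).size < 2:
                raise ValueError(f"variable {var!r} has zero variance; cannot scale")
            rows.append(dict(variable=var, mean=float(np.mean(x)), sd=float(np.std(x, ddof=1))))
        scaling = pd.DataFrame(rows)
    table = scaling.set_index("variable")
    for var in variables:
        if var not in table.index:
            raise ValueError(f"no scaling entry for variable {var!r}")
        m, s = table.loc[var, "mean"], table.loc[var, "sd"]
        if s <= 0:
            raise ValueError(f"non-positive SD in scaling entry for {var!r}")
        out[f"{var}_scaled"] = (out[var].to_numpy(float) - m) / s
    return out, scaling


def unscale_covariates(steps: pd.DataFrame, scaling: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`scale_covariates` (drops nothing; recomputes raw columns)."""
    out = steps.copy()
    for _, row in scaling.iterrows():
        var = row["variable"]
        col = f"{var}_scaled"
        if col in out.columns:
            out[var] = out[col].to_numpy(float) * row["sd"] + row["mean"]
    return out


def collinearity_screen(
    steps: pd.DataFrame, variables: list[str], threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Pearson correlations with an advisory collinearity flag.

    Pairs with |r| strictly above the threshold are flagged; constant
    variables yield NaN correlations (reported, not flagged).  The screen
    warns — dropping a variable is the model builder's decision.
    """
    if len(steps) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            x = steps[a].to_numpy(float)
            y = steps[b].to_numpy(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            # strictly-above flagging, with a guard against float noise at the boundary
            flagged = bool(np.abs(r) > threshold + 1e-12) if np.isfinite(r) else False
            rows.append(dict(var_a=a, var_b=b, r=r, flagged=flagged))
    return pd.DataFrame(rows)
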