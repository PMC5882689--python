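"""Observed and alternative steps for the matched case-control design.

A *step* is the straight-line (great-circle) segment between consecutive
telemetry fixes.  Each observed step becomes the case of a stratum; its
M alternatives share the start point and start time and draw their
length and turning angle, independently and with replacement, from the
pooled empirical distributions of the observed steps.  Tracks are first
thinned so consecutive fixes are at least ``min_gap`` apart, which damps
serial autocorrelation.

Step tables are pandas DataFrames with the columns in
:data:`oceanssf.io.STEP_COLUMNS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geodesy


def thin_track(track: pd.DataFrame, min_gap_hours: float = 1.0) -> pd.DataFrame:
    """Greedy temporal thinning, per individual.

    Scanning from the first fix, a fix is kept iff it is at least
    ``min_gap_hours`` after the last kept fix.  Idempotent; preserves order.
    """
    if len(track) == 0:
        return track.copy()
    gap = pd.Timedelta(hours=min_gap_hours)
    kept_parts = []
    for _, grp in track.groupby("individual_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        keep = []
        last = None
        for idx, t in zip(grp.index, grp["timestamp"]):
            if last is None or t - last >= gap:
                keep.append(idx)
                last = t
        kept_parts.append(grp.loc[keep])
    return pd.concat(kept_parts).reset_index(drop=True)


def build_observed_steps(track: pd.DataFrame) -> pd.DataFrame:
    """One case step per consecutive fix pair, per individual.

    Stratum ids are assigned sequentially across individuals; strata
    never span individuals.  The turning angle is defined from each
    individual's second step onward (NaN on first steps).
    """
    rows = []
    stratum = 0
    for ind, grp in track.groupby("individual_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        if len(grp) < 2:
            continue
        lat = grp["location_lat"].to_numpy(float)
        lon = grp["location_long"].to_numpy(float)
        length = geodesy.gc_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
        heading = geodesy.initial_bearing(lat[:-1], lon[:-1], lat[1:], lon[1:])
        turn = np.full(len(grp) - 1, np.nan)
        turn[1:] = geodesy.turning_angle(heading[:-1], heading[1:])
        for i in range(len(grp) - 1):
            rows.append(
                dict(
                    stratum_id=stratum,
                    is_case=True,
                    ind_id=ind,
                    t_start=grp["timestamp"].iloc[i],
                    t_end=grp["timestamp"].iloc[i + 1],
                    lat1=lat[i], lon1=lon[i], lat2=lat[i + 1], lon2=lon[i + 1],
                    length_km=float(np.atleast_1d(length)[i]),
                    heading_deg=float(np.atleast_1d(heading)[i]),
                    turn_deg=float(turn[i]),
                )
            )
            stratum += 1
    return pd.DataFrame(rows)


def sample_alternative_steps(
    case: pd.Series,
    lengths: np.ndarray,
    turns: np.ndarray,
    M: int = 100,
    rng: np.random.Generator | None = None,
    prev_heading: float | None = None,
) -> pd.DataFrame:
    """M alternative steps from the case's start point.

    Length and turn are drawn independently, with replacement, from the
    supplied empirical samples (raw values, no binning or smoothing).
    Endpoints lie at ``destination_point(start, prev_heading + turn, length)``.
    For a track's first step, where no previous heading exists, the case
    step's own heading is the reference direction.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    lengths = np.asarray(lengths, dtype=float)
    turns = np.asarray(turns, dtype=float)
    if lengths.size == 0 or turns.size == 0:
        raise ValueError("empirical length/turn samples must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    if prev_heading is None:
        prev_heading = float(case["heading_deg"])
    L = rng.choice(lengths, size=M, replace=True)
    T = rng.choice(turns, size=M, replace=True)
    head = (prev_heading + T) % 360.0
    lat2, lon2 = geodesy.destination_point(case["lat1"], case["lon1"], head, L)
    return pd.DataFrame(
        dict(
            stratum_id=case["stratum_id"],
            is_case=False,
            ind_id=case["ind_id"],
            t_start=case["t_start"],
            t_end=case["t_end"],
            lat1=case["lat1"], lon1=case["lon1"], lat2=lat2, lon2=lon2,
            length_km=L,
            heading_deg=head,
            turn_deg=T,
        )
    )


def assemble_strata(cases: pd.DataFrame, alt_lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Interleave cases with their alternative sets into one step table.

    Validates the matched design: one alternatives table per case, all
    alternatives sharing the case's start point/time, unique stratum ids.
    """
    if len(cases) != len(alt_lists):
        raise ValueError(f"{len(cases)} cases but {len(alt_lists)} alternative sets")
    if cases["stratum_id"].duplicated().any():
        raise ValueError("duplicate stratum_id among cases")
    parts = []
    for (_, case), alts in zip(cases.iterrows(), alt_lists):
        if (alts["stratum_id"] != case["stratum_id"]).any():
            raise ValueError(f"alternatives mislabelled for stratum {case['stratum_id']}")
        if not (
            np.allclose(alts["lat1"], case["lat1"])
            and np.allclose(alts["lon1"], case["lon1"])
            and (alts["t_start"] == case["t_start"]).all()
        ):
            raise ValueError(f"alternatives do not share start of stratum {case['stratum_id']}")
        parts.append(pd.DataFrame([case]))
        parts.append(alts)
    out = pd.concat(parts, ignore_index=True)
    out["is_case"] = out["is_case"].astype(bool)
    return out


def generate_steps(
    track: pd.DataFrame,
    min_gap_hours: float = 1.0,
    n_alternatives: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Full observed+alternative step table for a (multi-individual) track.

    Thins the track, builds observed steps, pools their empirical
    length/turn distributions across individuals, and samples
    ``n_alternatives`` per stratum.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    thinned = thin_track(track, min_gap_hours)
    cases = build_observed_steps(thinned)
    if len(cases) == 0:
        return cases
    lengths = cases["length_km"].to_numpy(float)
    turns = cases["turn_deg"].to_numpy(float)
    turns = turns[np.isfinite(turns)]
    if turns.size == 0:  # single-step tracks only: no observed turns exist
        turns = np.array([0.0])
    alt_lists = []
    prev_by_ind: dict = {}
    for _, case in cases.iterrows():
        prev = prev_by_ind.get(case["ind_id"])
        alt_lists.append(
            sample_alternative_steps(case, lengths, turns, n_alternatives, rng, prev)
        )
        prev_by_ind[case["ind_id"]] = float(case["heading_deg"])
    return assemble_strata(cases, alt_lists)
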