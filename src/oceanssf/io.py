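"""CSV interchange: telemetry tracks, step tables, external step tables.

Tracks use Movebank-style columns (``individual_id, timestamp,
location_lat, location_long``, timestamps ISO-8601 UTC).  All writers can
prepend ``#``-prefixed provenance comment lines; all readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TRACK_COLUMNS = ["individual_id", "timestamp", "location_lat", "location_long"]

STEP_COLUMNS = [
    "stratum_id", "is_case", "ind_id", "t_start", "t_end",
    "lat1", "lon1", "lat2", "lon2", "length_km", "heading_deg", "turn_deg",
]


def _write_csv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_track_csv(track: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    out = track[TRACK_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    _write_csv(out, path, header_lines)


def read_track_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_steps_csv(steps: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    out = steps.copy()
    for col in ("t_start", "t_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    _write_csv(out, path, header_lines)


def read_steps_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("t_start", "t_end"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=True).dt.tz_localize(None)
    if "is_case" in df.columns:
        df["is_case"] = df["is_case"].astype(bool)
    return df


def read_external_steps(
    path: str | Path,
    column_map: dict[str, str],
    true_values: tuple = (1, "1", True, "true", "TRUE", "yes"),
) -> pd.DataFrame:
    """Adapt an externally annotated step table to this package's layout.

    ``column_map`` maps this package's column names (``stratum_id``,
    ``is_case`` and covariate names such as ``dist_coast_km``) to the
    external file's headers, so supplementary tables with arbitrary
    headers can feed the fitting stage directly.
    """
    raw = pd.read_csv(path, comment="#")
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"{path}: mapped columns not found: {missing}")
    df = pd.DataFrame({ours: raw[theirs] for ours, theirs in column_map.items()})
    if "stratum_id" not in df.columns or "is_case" not in df.columns:
        raise ValueError("column_map must provide stratum_id and is_case")
    df["is_case"] = df["is_case"].isin(true_values)
    return df
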