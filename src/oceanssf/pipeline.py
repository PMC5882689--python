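"""End-to-end orchestration: simulate -> steps -> annotate -> fit -> validate -> lcp.

Configuration is TOML; one global seed is expanded into per-stage
generators via ``numpy.random.default_rng([seed, stage_index])`` (stage
indices are fixed constants), so any stage can be reproduced in
isolation.  Every artifact carries a provenance header (package version,
stage, seed, config hash) and the run emits a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, io, steps as steps_mod, synthetic
from .cost_path import conductance_surface, distance_to_coast, least_cost_path
from .raster import read_ascii_grid, read_wind_field, write_ascii_grid, write_wind_field
from .ssf_model import backward_select, fit_clogit
from .validation import kfold_case_control_cv, permutation_importance

log = logging.getLogger("oceanssf")

STAGE_SEEDS = {"simulate": 10, "steps": 11, "validate": 13, "importance": 14}

MODEL_VARS = ["dist_coast_km", "wind_support_ms", "crosswind_ms"]
AUX_VARS = ["blh_m", "cloud_frac", "rh_pct"]

FULL_TERMS = [
    "dist_coast_km_scaled",
    "wind_support_ms_scaled",
    "crosswind_ms_scaled",
    "blh_m_scaled",
    "cloud_frac_scaled",
    "rh_pct_scaled",
    "dist_coast_km_scaled:crosswind_ms_scaled",
    "dist_coast_km_scaled:wind_support_ms_scaled",
]


def parse_formula(formula: str) -> list[str]:
    """Terms of an R-style formula ``case ~ a + b + a:b + strata(stratum_id)``.

    The response and any ``strata(...)`` token are ignored (stratum ids
    always come from the ``stratum_id`` column).
    """
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    terms = []
    for raw in rhs.split("+"):
        t = raw.strip()
        if not t or t.startswith("strata(") or t == "1":
            continue
        terms.append(t)
    if not terms:
        raise ValueError(f"no terms found in formula {formula!r}")
    return terms


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def toml_dumps(config: dict, _prefix: str = "") -> str:
    """Minimal TOML writer for nested dicts of scalars/lists (round-trips via tomllib)."""
    lines, tables = [], []
    for key, val in config.items():
        if isinstance(val, dict):
            tables.append((key, val))
        else:
            lines.append(f"{key} = {_toml_value(val)}")
    out = "\n".join(lines)
    for key, val in tables:
        name = f"{_prefix}{key}"
        out += f"\n\n[{name}]\n" + toml_dumps(val, _prefix=f"{name}.").lstrip("\n")
    return out.strip() + "\n"


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_sha(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance(config: dict, stage: str) -> list[str]:
    return [
        f"oceanssf {__version__} stage={stage}",
        f"seed={config.get('seed', 0)} config_sha={config_sha(config)}",
    ]


def _stage_rng(config: dict, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.get("seed", 0)), STAGE_SEEDS[stage]])


def write_track_geojson(track: pd.DataFrame, path: Path) -> None:
    coords = [[float(x), float(y)] for x, y in zip(track["location_long"], track["location_lat"])]
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"kind": "track"}, "geometry": {"type": "LineString", "coordinates": coords}}
        ],
    }
    path.write_text(json.dumps(gj))


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; return the artifact manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "seed": seed,
        "config_sha": config_sha(config),
        "version": __version__,
        "stages": {},
        "artifacts": [],
    }

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = dict(seconds=round(time.time() - t0, 3), **info)

    def artifact(p: Path) -> None:
        manifest["artifacts"].append(str(p))

    state: dict = {}

    def run_stage(name: str, fn) -> None:
        cfg = config.get(name, {})
        if not cfg.get("enabled", True):
            log.info("stage %s skipped", name)
            return
        t0 = time.time()
        try:
            fn(cfg, t0)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    # ---- simulate -------------------------------------------------------
    def do_simulate(cfg, t0):
        sim_kwargs = {k: v for k, v in cfg.items() if k != "enabled"}
        sim = synthetic.SimConfig.from_dict({**sim_kwargs, "seed": seed})
        mask = synthetic.make_archipelago(sim)
        dcoast = distance_to_coast(mask)
        times = synthetic.wind_times_for(sim)
        wind = synthetic.make_wind_field(sim, times)
        aux = synthetic.make_aux_fields(sim, times)
        track = synthetic.simulate_track(sim, dcoast, wind)
        write_ascii_grid(mask, out_dir / "mask.asc")
        write_ascii_grid(dcoast, out_dir / "dcoast.asc")
        write_wind_field(wind, out_dir / "wind")
        io.write_track_csv(track, out_dir / "track.csv", provenance(config, "simulate"))
        for p in ("mask.asc", "dcoast.asc", "track.csv"):
            artifact(out_dir / p)
        artifact(out_dir / "wind")
        state.update(sim=sim, mask=mask, dcoast=dcoast, wind=wind, aux=aux, track=track)
        record("simulate", t0, n_fixes=len(track))

    run_stage("simulate", do_simulate)

    # ---- steps ----------------------------------------------------------
    def do_steps(cfg, t0):
        if "track" not in state:
            state["track"] = io.read_track_csv(config["paths"]["track"])
        table = steps_mod.generate_steps(
            state["track"],
            min_gap_hours=float(cfg.get("min_gap_hours", 1.0)),
            n_alternatives=int(cfg.get("n_alternatives", 100)),
            rng=_stage_rng(config, "steps"),
        )
        io.write_steps_csv(table, out_dir / "steps.csv", provenance(config, "steps"))
        artifact(out_dir / "steps.csv")
        state["steps"] = table
        record("steps", t0, n_strata=int(table["stratum_id"].nunique()), n_rows=len(table))

    run_stage("steps", do_steps)

    # ---- annotate -------------------------------------------------------
    def do_annotate(cfg, t0):
        if "dcoast" not in state:
            state["dcoast"] = read_ascii_grid(config["paths"]["dcoast"])
        if "wind" not in state:
            wind_dir = Path(config["paths"]["wind_dir"])
            if not wind_dir.is_dir():
                raise FileNotFoundError(f"wind directory {wind_dir} not found")
            state["wind"] = read_wind_field(wind_dir)
        if "steps" not in state:
            state["steps"] = io.read_steps_csv(config["paths"]["steps"])
        annotated = annotation.annotate_steps(
            state["steps"], state["dcoast"], state["wind"],
            aux=state.get("aux"), at=cfg.get("at", "end"),
        )
        variables = [v for v in MODEL_VARS + AUX_VARS if v in annotated.columns]
        annotated, scaling = annotation.scale_covariates(annotated, variables)
        screen = annotation.collinearity_screen(annotated, variables)
        io.write_steps_csv(annotated, out_dir / "annotated.csv", provenance(config, "annotate"))
        scaling.to_csv(out_dir / "scaling.csv", index=False)
        screen.to_csv(out_dir / "collinearity.csv", index=False)
        for p in ("annotated.csv", "scaling.csv", "collinearity.csv"):
            artifact(out_dir / p)
        state["annotated"] = annotated
        n_flagged = int(screen["flagged"].sum())
        if n_flagged:
            log.warning("collinearity screen flagged %d variable pairs", n_flagged)
        record("annotate", t0, n_rows=len(annotated), collinear_pairs=n_flagged)

    run_stage("annotate", do_annotate)

    # ---- fit ------------------------------------------------------------
    def do_fit(cfg, t0):
        table = state["annotated"]
        terms = cfg.get("terms") or [t for t in FULL_TERMS if _terms_present(table, t)]
        if cfg.get("stepwise", True):
            trace = backward_select(table, terms, alpha=float(cfg.get("alpha", 0.05)))
            trace.table().to_csv(out_dir / "model_trace.csv", index=False)
            artifact(out_dir / "model_trace.csv")
            best = trace.best
        else:
            best = fit_clogit(table, terms)
        (out_dir / "fit.json").write_text(json.dumps(best.to_dict(), indent=2))
        artifact(out_dir / "fit.json")
        state["fit"] = best
        record("fit", t0, n_terms=len(best.terms), aic=best.aic)

    run_stage("fit", do_fit)

    # ---- validate -------------------------------------------------------
    def do_validate(cfg, t0):
        table = state["annotated"]
        best = state["fit"]
        cv = kfold_case_control_cv(
            table, best.terms,
            k=int(cfg.get("k", 5)), n_bins=int(cfg.get("n_bins", 10)),
            reps=int(cfg.get("reps", 100)), rng=_stage_rng(config, "validate"),
        )
        (out_dir / "cv.json").write_text(json.dumps(cv.to_dict(), indent=2))
        imp = permutation_importance(
            table, best, n_perm=int(cfg.get("n_perm", 10)),
            rng=_stage_rng(config, "importance"),
        )
        (out_dir / "importance.json").write_text(json.dumps(imp.to_dict(), indent=2))
        artifact(out_dir / "cv.json")
        artifact(out_dir / "importance.json")
        record("validate", t0, r_observed=cv.r_observed_mean, r_chance=cv.r_chance_mean)

    run_stage("validate", do_validate)

    # ---- least-cost path ------------------------------------------------
    def do_lcp(cfg, t0):
        dcoast = state.get("dcoast") or read_ascii_grid(config["paths"]["dcoast"])
        eps = cfg.get("epsilon")
        cond = conductance_surface(dcoast, float(eps) if eps else None)
        if "start" in cfg:
            start = tuple(cfg["start"])
            end = tuple(cfg["end"])
        else:  # default: last mainland fix to first destination fix is user business;
            # fall back to the track's endpoints
            track = state["track"]
            start = (float(track["location_lat"].iloc[0]), float(track["location_long"].iloc[0]))
            end = (float(track["location_lat"].iloc[-1]), float(track["location_long"].iloc[-1]))
        res = least_cost_path(cond, *start, *end, neighbors=int(cfg.get("neighbors", 8)))
        path_df = pd.DataFrame(
            dict(order=np.arange(len(res)), lat=res.path_lat, lon=res.path_lon, cum_cost=res.cum_cost)
        )
        path_df.to_csv(out_dir / "lcp_path.csv", index=False)
        artifact(out_dir / "lcp_path.csv")
        if "track" in state:
            write_track_geojson(state["track"], out_dir / "track.geojson")
            artifact(out_dir / "track.geojson")
        state["lcp"] = res
        record("lcp", t0, n_cells=len(res), total_cost=res.total_cost)

    run_stage("lcp", do_lcp)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _terms_present(table: pd.DataFrame, term: str) -> bool:
    return all(f in table.columns for f in term.split(":"))
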