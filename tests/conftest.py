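"""Shared fixtures: one synthetic world reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import oceanssf as o

TERMS = [
    "dist_coast_km_scaled",
    "wind_support_ms_scaled",
    "crosswind_ms_scaled",
    "dist_coast_km_scaled:wind_support_ms_scaled",
]

MODEL_VARS = ["dist_coast_km", "wind_support_ms", "crosswind_ms"]


@pytest.fixture(scope="session")
def sim_cfg():
    return o.SimConfig(seed=0)


@pytest.fixture(scope="session")
def world(sim_cfg):
    """(cfg, mask, dcoast, wind) for the default synthetic archipelago."""
    mask = o.make_archipelago(sim_cfg)
    dcoast = o.distance_to_coast(mask)
    wind = o.make_wind_field(sim_cfg, o.wind_times_for(sim_cfg))
    return sim_cfg, mask, dcoast, wind


@pytest.fixture(scope="session")
def recorded_track(world):
    """A 61-stratum SSF-driven track with its internal choice sets."""
    cfg, _mask, dcoast, wind = world
    track, strata = o.simulate_track(cfg, dcoast, wind, record_choices=True)
    return track, strata


@pytest.fixture(scope="session")
def scaled_strata(world, recorded_track):
    """Choice-set strata scaled on the generator's declared truth scale."""
    cfg = world[0]
    _track, strata = recorded_track
    scaled, _ = o.scale_covariates(strata, MODEL_VARS, scaling=o.truth_scaling_table(cfg))
    return scaled


def make_random_strata(rng, n_strata=6, max_size=6, n_terms=2, beta=None, min_size=2):
    """Small random matched design for likelihood oracles."""
    rows = []
    for s in range(n_strata):
        size = rng.integers(min_size, max_size + 1)
        X = rng.normal(size=(size, n_terms))
        if beta is None:
            case = rng.integers(size)
        else:
            eta = X @ beta
            p = np.exp(eta - eta.max())
            p /= p.sum()
            case = rng.choice(size, p=p)
        for j in range(size):
            rows.append(
                dict(stratum_id=s, is_case=j == case, **{f"x{k}": X[j, k] for k in range(n_terms)})
            )
    return pd.DataFrame(rows)
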