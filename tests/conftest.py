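"""Shared fixtures: canonical scenarios and simulated tag series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from divetag import dives as dv
from divetag import synthetic as syn

COLD_SCENARIO = {
    # coastal-upwelling-like: cold at depth, high background attenuation
    "surface_temp": 15.5,
    "deep_temp": 7.0,
    "mld_true": 35.0,
    "thermocline_width": 8.0,
    "latitude": 45.0,
    "longitude": 230.0,
    "attenuation": [
        {"kind": "background", "k0": 0.041},
        {"kind": "dcm", "peak_k": 0.02, "center_depth": 70.0, "width": 15.0},
        {"kind": "scattering_layer", "peak_k": 0.06, "center_depth": 250.0,
         "width": 25.0},
    ],
}

WARM_SCENARIO = {
    # subtropical-gyre-like: warm at depth, clear water, layer at 250 m
    "surface_temp": 17.0,
    "deep_temp": 11.0,
    "mld_true": 55.0,
    "thermocline_width": 10.0,
    "latitude": 30.0,
    "longitude": 210.0,
    "attenuation": [
        {"kind": "background", "k0": 0.035},
        {"kind": "dcm", "peak_k": 0.02, "center_depth": 110.0, "width": 15.0},
        {"kind": "scattering_layer", "peak_k": 0.06, "center_depth": 250.0,
         "width": 25.0},
    ],
}


def make_scenario(which: str = "cold", **overrides) -> syn.OceanScenario:
    cfg = dict(COLD_SCENARIO if which == "cold" else WARM_SCENARIO)
    cfg.update(overrides)
    return syn.build_scenario(cfg)


def make_behavior(**overrides) -> syn.BehaviorConfig:
    kwargs = dict(
        n_days=2,
        u_dives_per_day=3,
        v_dives_per_day=3,
        u_target_layer=2,
        sampling_interval_s=30,
        light_sd=0.01,
        seed=0,
    )
    kwargs.update(overrides)
    return syn.BehaviorConfig(**kwargs)


def noiseless(**overrides) -> syn.BehaviorConfig:
    kwargs = dict(depth_sd=0.0, temp_sd=0.0, light_sd=0.0)
    kwargs.update(overrides)
    return make_behavior(**kwargs)


def toy_series(
    depth: np.ndarray,
    temp: np.ndarray | None = None,
    light: np.ndarray | None = None,
    dt_s: float = 30.0,
    start: str = "2019-06-15T20:00:00Z",
    lat: float = 45.0,
    lon: float = 230.0,
    fish_length: float = 0.8,
) -> syn.TagSeries:
    """Hand-built TagSeries around an explicit depth vector."""
    depth = np.asarray(depth, dtype=float)
    n = depth.size
    ts = pd.date_range(start=start, periods=n, freq=f"{int(dt_s)}s", tz="UTC")
    data = pd.DataFrame(
        {
            "timestamp": ts,
            "depth_m": depth,
            "temp_c": np.full(n, 10.0) if temp is None else np.asarray(temp, float),
        }
    )
    if light is not None:
        data["light"] = np.asarray(light, dtype=float)
    dates = sorted(set(ts.date))
    positions = pd.DataFrame({"date": dates, "lat": lat, "lon": lon})
    return syn.TagSeries(
        data=data, positions=positions, fish_length=fish_length, fish_id="toy"
    )


@pytest.fixture(scope="session")
def cold_series() -> syn.TagSeries:
    return syn.simulate_tag_series(make_scenario("cold"), make_behavior(seed=11))


@pytest.fixture(scope="session")
def cold_profiling_series() -> syn.TagSeries:
    return syn.simulate_tag_series(
        make_scenario("cold"),
        make_behavior(seed=7, n_days=1, profiling_excursion=True),
    )


@pytest.fixture(scope="session")
def dcm_table() -> dv.DCMTable:
    return dv.DEFAULT_DCM_TABLE
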