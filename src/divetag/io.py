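"""Readers and writers for the package's delimited-text interchange formats.

Tag series: CSV with header ``timestamp,depth_m,temp_c,light`` (ISO-8601
UTC timestamps). Positions: CSV ``date,lat,lon``. Backscatter: long-format
CSV ``hour,depth_m,sv_db`` (plus optional day/lat/lon columns).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from divetag.dives import DCMTable
from divetag.synthetic import BehaviorConfig, OceanScenario, TagSeries, build_scenario

__all__ = [
    "write_tag_series",
    "read_tag_series",
    "write_backscatter",
    "read_backscatter",
    "load_scenario",
    "load_behavior",
    "load_dcm_table",
]


def write_tag_series(series: TagSeries, series_path, positions_path) -> None:
    df = series.data.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(series_path, index=False)
    series.positions.to_csv(positions_path, index=False)


def read_tag_series(
    series_path,
    positions_path,
    fish_length: float = 0.8,
    fish_id: str = "fish0",
    light_channel: str = "log",
) -> TagSeries:
    df = pd.read_csv(series_path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    pos = pd.read_csv(positions_path)
    pos["date"] = pd.to_datetime(pos["date"]).dt.date
    return TagSeries(
        data=df,
        positions=pos,
        fish_length=fish_length,
        fish_id=fish_id,
        light_channel=light_channel,
    )


def write_backscatter(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_backscatter(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_scenario(path) -> OceanScenario:
    with open(path) as fh:
        return build_scenario(yaml.safe_load(fh))


def load_behavior(path) -> BehaviorConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "start_date" in cfg:
        cfg["start_date"] = pd.to_datetime(cfg["start_date"]).date()
    for key in ("u_bottom_duration_min", "v_apex_depth", "descent_rate",
                "ascent_rate", "surface_depth"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return BehaviorConfig(**cfg)


def load_dcm_table(path) -> DCMTable:
    """DCM table YAML: {bands: {<lat band edge>: {mean: m, sd: m}, ...}}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    bands = {
        int(k): (float(v["mean"]), float(v["sd"])) for k, v in cfg["bands"].items()
    }
    return DCMTable(bands=bands)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
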