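"""Diel backscatter composites, scattering-layer traces, and dive overlays.

Profiles (long format: local solar hour or UTC timestamp, depth, mean
volume backscatter in dB) are pooled into an hour-of-day x depth-bin grid.
Cells with no observations are missing, never zero-filled. Local solar
hour is UTC + lon/15 rounded to the integer hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ADCPComposite",
    "LayerTrace",
    "composite_diel",
    "trace_layers",
    "overlay_dive_quartiles",
]

DAY_HOURS = (6, 18)  # [6, 18) is daytime in composites


@dataclass
class ADCPComposite:
    region: str
    hours: np.ndarray  # 0..23
    depth_bins: np.ndarray  # bin centers, m
    grid: np.ndarray  # (24, n_bins) mean sv dB; NaN = missing
    n_profiles: np.ndarray  # observation count per cell


@dataclass
class LayerTrace:
    stratum: tuple[float, float]
    centroid: np.ndarray  # per hour, m (NaN where stratum empty)
    peak: np.ndarray  # per hour, m


def composite_diel(
    profiles: pd.DataFrame,
    region_box=None,
    depth_bin_width: float = 10.0,
    depth_max: float = 600.0,
    region_name: str = "",
) -> ADCPComposite:
    """Mean backscatter per (local hour, depth bin) cell.

    ``profiles`` needs columns depth_m, sv_db and either ``hour`` (local
    solar hour) or ``timestamp`` + ``lon``. ``region_box`` (optional) is a
    ProvinceBox-like object used to subset by lat/lon columns.
    """
    df = profiles
    if region_box is not None:
        keep = [
            region_box.contains(la, lo % 360.0)
            for la, lo in zip(df["lat"], df["lon"])
        ]
        df = df.loc[keep]
    if df.empty:
        raise ValueError(f"no profiles within region {region_name or region_box}")
    if "hour" in df.columns:
        hour = df["hour"].to_numpy(int) % 24
    else:
        utc_h = pd.to_datetime(df["timestamp"], utc=True).dt.hour.to_numpy()
        utc_m = pd.to_datetime(df["timestamp"], utc=True).dt.minute.to_numpy()
        hour = np.rint(utc_h + utc_m / 60.0 + df["lon"].to_numpy(float) / 15.0)
        hour = hour.astype(int) % 24

    depth = df["depth_m"].to_numpy(float)
    sv = df["sv_db"].to_numpy(float)
    nbins = int(np.ceil(depth_max / depth_bin_width))
    dbin = np.clip((depth // depth_bin_width).astype(int), 0, nbins - 1)

    grid = np.full((24, nbins), np.nan)
    counts = np.zeros((24, nbins), dtype=int)
    sums = np.zeros((24, nbins))
    np.add.at(sums, (hour, dbin), sv)
    np.add.at(counts, (hour, dbin), 1)
    nz = counts > 0
    grid[nz] = sums[nz] / counts[nz]
    centers = (np.arange(nbins) + 0.5) * depth_bin_width
    return ADCPComposite(
        region=region_name,
        hours=np.arange(24),
        depth_bins=centers,
        grid=grid,
        n_profiles=counts,
    )


def trace_layers(
    composite: ADCPComposite, strata: list[tuple[float, float]]
) -> list[LayerTrace]:
    """Backscatter-weighted centroid and peak depth per hour, per stratum.

    Weights are linearized backscatter (10**(sv/10)) so traces follow the
    acoustic energy, not the dB offset. Hours with an all-missing stratum
    give NaN trace points.
    """
    traces = []
    for zmin, zmax in strata:
        if zmin >= zmax or zmax > composite.depth_bins[-1] + 5.0 or zmin < 0:
            raise ValueError(f"stratum ({zmin}, {zmax}) outside the grid")
        sel = (composite.depth_bins >= zmin) & (composite.depth_bins <= zmax)
        z = composite.depth_bins[sel]
        centroid = np.full(24, np.nan)
        peak = np.full(24, np.nan)
        for h in range(24):
            sv = composite.grid[h, sel]
            ok = np.isfinite(sv)
            if not ok.any():
                continue
            w = 10.0 ** (sv[ok] / 10.0)
            centroid[h] = float((w * z[ok]).sum() / w.sum())
            peak[h] = float(z[ok][np.argmax(sv[ok])])
        traces.append(LayerTrace(stratum=(zmin, zmax), centroid=centroid, peak=peak))
    return traces


def overlay_dive_quartiles(
    composite: ADCPComposite, max_depths: np.ndarray
) -> dict[str, float] | None:
    """Quartiles (linear-interpolation convention) of daytime dive depths.

    Emits a warning (but still returns quartiles) below 4 dives; returns
    None for an empty set, leaving the composite unchanged.
    """
    d = np.asarray(max_depths, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return None
    if d.size < 4:
        import warnings

        warnings.warn(f"only {d.size} dives for quartile overlay")
    q25, q50, q75 = np.quantile(d, [0.25, 0.5, 0.75])  # numpy default = type-7
    return {"q25": float(q25), "q50": float(q50), "q75": float(q75)}
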