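"""Mixed-layer estimation, dive extraction, segmentation, and classification.

Dives are referenced to the mixed layer: a dive starts and ends where depth
crosses ``mld + offset`` (default 10 m below the estimated mixed layer
depth). Phases follow the 75%-of-max-depth rule: the bottom phase spans the
first to the last sample at depth >= 0.75 * max_depth; descent and ascent
are everything before and after. Daytime deep dives are retained if they
fall between local sunrise and sunset and exceed the latitude band's deep
chlorophyll maximum (DCM) cutoff, so chlorophyll cannot confound deeper
analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from divetag import solar
from divetag.synthetic import TagSeries

__all__ = [
    "MLDEstimate",
    "Dive",
    "DiveMetrics",
    "DCMTable",
    "InsufficientDataError",
    "estimate_mld",
    "estimate_mld_by_day",
    "extract_dives",
    "segment_phases",
    "filter_daytime_deep",
    "classify_dives",
    "classify_dive_rule",
    "compute_dive_metrics",
    "dives_to_frame",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class MLDEstimate:
    date: _date
    mld: float
    method_tag: str
    n_samples_used: int
    ml_temp: float  # mean temperature above the MLD that day
    flagged: bool = False  # threshold never crossed


@dataclass
class Dive:
    """One extracted dive; index ranges point into the source TagSeries."""

    dive_id: int
    fish_id: str
    date: _date
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    samples: tuple[int, int]  # inclusive index range
    max_depth: float = np.nan
    descent: tuple[int, int] | None = None
    bottom: tuple[int, int] | None = None
    ascent: tuple[int, int] | None = None
    descent_duration: float = np.nan  # minutes
    bottom_duration: float = np.nan
    ascent_duration: float = np.nan
    total_duration: float = np.nan
    bottom_proportion: float = np.nan
    class_label: str = "other"
    degenerate: bool = False


@dataclass(frozen=True)
class DiveMetrics:
    min_temp: float
    delta_temp: float
    descent_rate: float  # m/s
    delta_light: float | None  # orders of magnitude (log10), negative
    daytime: bool | None
    light_missing: bool = False


@dataclass(frozen=True)
class DCMTable:
    """Per-10-degree-latitude-band DCM depth statistics.

    ``bands`` maps the band's lower latitude edge (a multiple of 10) to
    ``(mean_dcm_depth_m, sd_m)``; the usable cutoff is ``mean + 3*sd``.
    """

    bands: dict[int, tuple[float, float]]

    def band_of(self, lat: float) -> int:
        return int(np.floor(lat / 10.0) * 10)

    def cutoff(self, lat: float) -> float:
        band = self.band_of(lat)
        if band not in self.bands:
            raise KeyError(f"no DCM entry for latitude band [{band}, {band + 10})")
        mean, sd = self.bands[band]
        return mean + 3.0 * sd


# Placeholder defaults spanning the mid-latitude study range; editable config.
DEFAULT_DCM_TABLE = DCMTable(
    bands={
        20: (110.0, 25.0),
        30: (100.0, 20.0),
        40: (70.0, 18.0),
        50: (55.0, 15.0),
    }
)


def estimate_mld(
    day_records: pd.DataFrame,
    delta_t_threshold: float = 0.5,
    bin_width: float = 5.0,
    date: _date | None = None,
) -> MLDEstimate:
    """Temperature-threshold MLD from a daily median binned profile.

    MLD is the shallowest 5-m bin whose median temperature falls more than
    ``delta_t_threshold`` below the 0-10 m reference. If no bin qualifies
    the deepest binned depth is returned with ``flagged=True``.
    """
    depth = day_records["depth_m"].to_numpy(float)
    temp = day_records["temp_c"].to_numpy(float)
    ok = np.isfinite(depth) & np.isfinite(temp)
    depth, temp = depth[ok], temp[ok]
    if depth.size < 20 or (depth.max() - depth.min()) < 30.0:
        raise InsufficientDataError(
            f"need >= 20 samples spanning >= 30 m; got n={depth.size}, "
            f"span={0.0 if depth.size == 0 else depth.max() - depth.min():.1f} m"
        )
    if date is None:
        date = pd.Timestamp(day_records["timestamp"].iloc[0]).date()

    bins = np.floor(depth / bin_width).astype(int)
    prof = pd.DataFrame({"bin": bins, "temp": temp}).groupby("bin")["temp"].median()
    centers = prof.index.to_numpy() * bin_width + bin_width / 2.0

    ref_mask = centers <= 10.0
    if not ref_mask.any():
        ref_mask = centers == centers.min()
    ref = float(prof.to_numpy()[ref_mask].mean())

    below = prof.to_numpy() < ref - delta_t_threshold
    if below.any():
        mld = float(centers[below].min())
        flagged = False
    else:
        mld = float(centers.max())
        flagged = True
    above = depth <= mld
    ml_temp = float(temp[above].mean()) if above.any() else ref
    return MLDEstimate(
        date=date,
        mld=mld,
        method_tag=f"temp_threshold_{delta_t_threshold}C",
        n_samples_used=int(depth.size),
        ml_temp=ml_temp,
        flagged=flagged,
    )


def estimate_mld_by_day(
    series: TagSeries, delta_t_threshold: float = 0.5, bin_width: float = 5.0
) -> dict[_date, MLDEstimate]:
    """MLD estimate per calendar day; days with too little data are skipped."""
    out: dict[_date, MLDEstimate] = {}
    for day, grp in series.data.groupby(series.data["timestamp"].dt.date):
        try:
            out[day] = estimate_mld(grp, delta_t_threshold, bin_width, date=day)
        except InsufficientDataError as exc:
            logger.warning("MLD skipped for %s: %s", day, exc)
    return out


def extract_dives(
    series: TagSeries,
    mld_by_day: dict[_date, MLDEstimate],
    offset: float = 10.0,
    min_duration_min: float = 5.0,
) -> list[Dive]:
    """Candidate dives: maximal runs of samples deeper than ``mld + offset``.

    Days without an MLD estimate are skipped with a logged warning.
    Candidates shorter than ``min_duration_min`` are dropped.
    """
    depth = series.data["depth_m"].to_numpy(float)
    dates = series.data["timestamp"].dt.date.to_numpy()
    threshold = np.full(depth.shape, np.inf)
    missing = set()
    for day in np.unique(dates):
        est = mld_by_day.get(day)
        if est is None:
            missing.add(day)
            continue
        threshold[dates == day] = est.mld + offset
    for day in sorted(missing):
        logger.warning("no MLD for %s; day skipped in dive extraction", day)

    mask = depth > threshold
    dt_s = series.sampling_interval_s
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = edges[mask[edges + 1]] + 1
    ends = edges[~mask[edges + 1]]
    if mask[0]:
        starts = np.insert(starts, 0, 0)
    if mask[-1]:
        ends = np.append(ends, mask.size - 1)

    ts = series.data["timestamp"]
    dives: list[Dive] = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        dur_min = (e - s + 1) * dt_s / 60.0
        if dur_min < min_duration_min:
            continue
        dives.append(
            Dive(
                dive_id=len(dives),
                fish_id=series.fish_id,
                date=dates[s],
                start_time=ts.iloc[s],
                end_time=ts.iloc[e],
                samples=(int(s), int(e)),
                max_depth=float(depth[s : e + 1].max()),
            )
        )
    return dives


def segment_phases(dive: Dive, series: TagSeries) -> Dive:
    """Assign descent/bottom/ascent phases by the 75%-of-max-depth rule."""
    s, e = dive.samples
    if e - s + 1 < 3:
        raise InsufficientDataError("dive needs >= 3 samples to segment")
    depth = series.data["depth_m"].to_numpy(float)[s : e + 1]
    dt_min = series.sampling_interval_s / 60.0
    max_depth = float(depth.max())
    thr = 0.75 * max_depth
    deep = np.flatnonzero(depth >= thr)
    b0, b1 = int(deep[0]), int(deep[-1])

    dive.max_depth = max_depth
    dive.bottom = (s + b0, s + b1)
    dive.descent = (s, s + b0 - 1) if b0 > 0 else None
    dive.ascent = (s + b1 + 1, e) if b1 < e - s else None
    dive.degenerate = dive.descent is None or dive.ascent is None

    dive.descent_duration = b0 * dt_min
    dive.bottom_duration = (b1 - b0 + 1) * dt_min
    dive.ascent_duration = (e - s - b1) * dt_min
    dive.total_duration = (e - s + 1) * dt_min
    dive.bottom_proportion = dive.bottom_duration / dive.total_duration
    return dive


def filter_daytime_deep(
    dives: list[Dive],
    positions: pd.DataFrame,
    dcm_table: DCMTable,
) -> tuple[list[Dive], dict[str, int]]:
    """Retain daytime dives deeper than the latitude band's DCM cutoff.

    Returns the retained list and per-rule rejection counts. A missing
    latitude band raises ``KeyError`` naming the band.
    """
    pos = positions.set_index("date")
    retained: list[Dive] = []
    rejections = {"not daytime": 0, "above DCM limit": 0, "no position": 0}
    for dv in dives:
        if dv.date not in pos.index:
            rejections["no position"] += 1
            continue
        lat = float(pos.loc[dv.date, "lat"])
        lon = float(pos.loc[dv.date, "lon"])
        cutoff = dcm_table.cutoff(lat)  # raises KeyError if band missing
        ev = solar.solar_events(dv.date, lat, lon)
        if not (dv.start_time >= ev.sunrise and dv.end_time <= ev.sunset):
            rejections["not daytime"] += 1
            continue
        if dv.max_depth <= cutoff:
            rejections["above DCM limit"] += 1
            continue
        retained.append(dv)
    return retained, rejections


def classify_dive_rule(dive: Dive) -> str:
    """Rule-mode U/V labels calibrated to the reported dive descriptors."""
    if dive.bottom_proportion >= 0.5 and dive.total_duration >= 10.0:
        return "U"
    if dive.bottom_proportion < 0.5 and 5.0 <= dive.total_duration <= 23.0:
        return "V"
    return "other"


def classify_dives(
    dives: list[Dive], mode: str = "cluster", seed: int = 0
) -> list[Dive]:
    """Label dives U or V.

    Default mode partitions (bottom_proportion, log total_duration) into two
    clusters on standardized features; the cluster with the higher mean
    bottom proportion is labeled U. With fewer than 2 dives (or
    ``mode='rule'``) a threshold rule is applied instead.
    """
    if mode not in ("cluster", "rule"):
        raise ValueError(f"unknown classification mode {mode!r}")
    if mode == "cluster" and len(dives) < 2:
        warnings.warn("fewer than 2 dives; falling back to rule-mode labels")
        mode = "rule"
    if mode == "rule":
        for dv in dives:
            dv.class_label = classify_dive_rule(dv)
        return dives

    feats = np.array(
        [[dv.bottom_proportion, np.log(dv.total_duration)] for dv in dives]
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    labels = km.labels_
    mean_bp = [feats[labels == c, 0].mean() for c in (0, 1)]
    u_cluster = int(np.argmax(mean_bp))
    for dv, lab in zip(dives, labels):
        dv.class_label = "U" if lab == u_cluster else "V"
    return dives


def compute_dive_metrics(
    dive: Dive,
    series: TagSeries,
    mld_estimate: MLDEstimate,
    daytime: bool | None = None,
) -> DiveMetrics:
    """Per-dive environmental metrics from the raw record.

    delta_light is in orders of magnitude (log10), from the dive start to
    the bottom-phase midpoint, honoring the series' declared light-channel
    semantics. If the light channel is absent the metric is None (flagged)
    and the temperature metrics are still computed.
    """
    if dive.bottom is None:
        raise ValueError("dive must be segmented before computing metrics")
    s, e = dive.samples
    temp = series.data["temp_c"].to_numpy(float)[s : e + 1]
    depth = series.data["depth_m"].to_numpy(float)[s : e + 1]
    min_temp = float(temp.min())
    delta_temp = min_temp - mld_estimate.ml_temp
    start_depth = float(depth[0])
    # rate over the descent phase: start depth to the first bottom-phase
    # sample; equals the vertical rate of a uniform descent
    if dive.descent_duration > 0:
        bottom_start_depth = float(depth[dive.bottom[0] - s])
        descent_rate = (bottom_start_depth - start_depth) / (
            dive.descent_duration * 60.0
        )
    else:
        descent_rate = np.nan

    delta_light: float | None = None
    light_missing = True
    if "light" in series.data.columns and series.data["light"].notna().any():
        light_missing = False
        light = series.data["light"].to_numpy(float)
        b0, b1 = dive.bottom
        mid = (b0 + b1) // 2
        if series.light_channel == "log":
            delta_light = float((light[mid] - light[s]) / np.log(10.0))
        else:
            delta_light = float(np.log10(light[mid]) - np.log10(light[s]))
    return DiveMetrics(
        min_temp=min_temp,
        delta_temp=delta_temp,
        descent_rate=float(descent_rate),
        delta_light=delta_light,
        daytime=daytime,
        light_missing=light_missing,
    )


def dives_to_frame(
    dives: list[Dive], metrics: list[DiveMetrics] | None = None
) -> pd.DataFrame:
    """Flatten dives (and optional metrics) into a tidy table."""
    rows = []
    for i, dv in enumerate(dives):
        row = {
            "dive_id": dv.dive_id,
            "fish_id": dv.fish_id,
            "date": dv.date,
            "start_time": dv.start_time,
            "end_time": dv.end_time,
            "max_depth_m": dv.max_depth,
            "descent_duration_min": dv.descent_duration,
            "bottom_duration_min": dv.bottom_duration,
            "ascent_duration_min": dv.ascent_duration,
            "total_duration_min": dv.total_duration,
            "bottom_proportion": dv.bottom_proportion,
            "class_label": dv.class_label,
        }
        if metrics is not None:
            m = metrics[i]
            row.update(
                {
                    "min_temp_c": m.min_temp,
                    "delta_temp_c": m.delta_temp,
                    "descent_rate_ms": m.descent_rate,
                    "delta_light_orders": m.delta_light,
                    "daytime": m.daytime,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
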