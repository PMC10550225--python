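"""Midday light-attenuation profiles and scattering-layer overlap detection.

A profile is built per fish-day from ln-irradiance observations within
solar noon +/- 1 hour, pooled over all vertical excursions in the window.
Attenuation k between adjacent depth bins is the negative slope of mean
ln-irradiance with depth. Deep increases in k below the latitude band's
DCM cutoff — where chlorophyll cannot confound the signal — are treated as
putative scattering-layer overlap (presence-only: no detection does not
mean no layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from divetag import solar
from divetag.dives import DCMTable, InsufficientDataError
from divetag.synthetic import TagSeries

__all__ = [
    "AttenuationProfile",
    "DetectionResult",
    "ProfileCluster",
    "AllDarkError",
    "build_attenuation_profile",
    "build_daily_profiles",
    "qc_profile",
    "detect_scattering_overlap",
    "cluster_profiles",
    "profiles_to_frame",
]


class AllDarkError(ValueError):
    """All light observations at the sensor floor; no gradient available."""


@dataclass
class AttenuationProfile:
    """Binned attenuation-vs-depth for one fish-day midday window.

    ``depth_bins`` are the midpoints between adjacent defined 5-m depth
    bins; ``k`` is the attenuation (1/m) across each pair; ``n_obs`` is the
    smaller of the two bins' observation counts.
    """

    fish_id: str
    date: _date
    lat: float
    lon: float
    depth_bins: np.ndarray
    k: np.ndarray
    n_obs: np.ndarray
    bin_width: float
    dcm_cutoff: float
    epipelagic_mean_k: float
    extends_below_cutoff: bool
    qc_pass: bool | None = None
    qc_flags: dict = field(default_factory=dict)

    @property
    def negative_fraction(self) -> float:
        if self.k.size == 0:
            return np.nan
        return float(np.mean(self.k < 0))


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the deep-attenuation-increase detector.

    ``overlap`` is None when preconditions failed (not evaluated) — that is
    distinct from an evaluated negative.
    """

    overlap: bool | None
    reference_min_k: float | None = None
    peak_depths: tuple[float, ...] = ()
    peak_excess: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.overlap is not None


@dataclass
class ProfileCluster:
    cluster_id: int
    members: list[int]  # indices into the input profile list
    depth_grid: np.ndarray
    composite_mean: np.ndarray
    composite_ci95: np.ndarray
    shallow_mean_k: float  # mean k over depths <= 100 m, for ordering


def pair_slopes(
    depth: np.ndarray, log_light: np.ndarray, min_pair_dz: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation estimates from consecutive-sample finite differences.

    Each pair of consecutive samples with a vertical separation of at least
    ``min_pair_dz`` contributes one estimate k = -dL/dz at the pair's
    midpoint depth. Consecutive samples are at most a minute apart, so the
    diel drift of surface light contributes negligibly to the difference
    (and with opposite sign on descents vs ascents).
    """
    dz = np.diff(depth)
    dl = np.diff(log_light)
    valid = np.abs(dz) >= min_pair_dz
    k = -dl[valid] / dz[valid]
    mid = (depth[:-1] + depth[1:])[valid] / 2.0
    return mid, k


def build_attenuation_profile(
    series: TagSeries,
    date: _date,
    lat: float,
    lon: float,
    dcm_cutoff: float,
    bin_width: float = 5.0,
    window_hours: float = 1.0,
    min_obs: int = 3,
    min_pair_dz: float = 3.0,
) -> AttenuationProfile:
    """Pool the fish-day's midday window into a binned attenuation profile.

    Per-pair slope estimates (see :func:`pair_slopes`) are averaged within
    fixed-width depth bins; bins with fewer than ``min_obs`` estimates are
    undefined. Negative k values are retained (QC flags them later).
    """
    ev = solar.solar_events(date, lat, lon)
    w = timedelta(hours=window_hours)
    ts = series.data["timestamp"]
    sel = series.data.loc[(ts >= ev.solar_noon - w) & (ts <= ev.solar_noon + w)]
    if sel.empty:
        raise InsufficientDataError(f"no samples in midday window on {date}")
    depth = sel["depth_m"].to_numpy(float)
    if depth.max() - depth.min() < 50.0:
        raise InsufficientDataError(
            f"midday depth span {depth.max() - depth.min():.0f} m < 50 m on {date}"
        )
    light = sel["light"].to_numpy(float)
    if series.light_channel == "linear":
        light = np.log(np.maximum(light, 1e-30))
    if np.nanstd(light) < 1e-3:
        raise AllDarkError(f"light channel flat (sensor floor) on {date}")

    mid, k_est = pair_slopes(depth, light, min_pair_dz)
    if mid.size == 0:
        raise InsufficientDataError(f"no vertical movement in midday window on {date}")
    bins = np.floor(mid / bin_width).astype(int)
    grp = pd.DataFrame({"bin": bins, "k": k_est}).groupby("bin")["k"]
    mean_k = grp.mean()
    counts = grp.size()
    defined = counts[counts >= min_obs].index.to_numpy()
    if defined.size < 2:
        raise InsufficientDataError(f"fewer than 2 occupied depth bins on {date}")
    centers = defined * bin_width + bin_width / 2.0
    k = mean_k.loc[defined].to_numpy()
    n_obs = counts.loc[defined].to_numpy()

    epi = (centers >= 20.0) & (centers <= 150.0)
    epipelagic_mean_k = float(k[epi].mean()) if epi.any() else np.nan
    return AttenuationProfile(
        fish_id=series.fish_id,
        date=date,
        lat=lat,
        lon=lon,
        depth_bins=centers,
        k=k,
        n_obs=n_obs,
        bin_width=bin_width,
        dcm_cutoff=dcm_cutoff,
        epipelagic_mean_k=epipelagic_mean_k,
        extends_below_cutoff=bool(centers.max() > dcm_cutoff),
    )


def build_daily_profiles(
    series: TagSeries, dcm_table: DCMTable, **kwargs
) -> list[AttenuationProfile]:
    """One profile per fish-day where the midday window has usable data."""
    out = []
    for _, row in series.positions.iterrows():
        day, lat, lon = row["date"], float(row["lat"]), float(row["lon"])
        try:
            out.append(
                build_attenuation_profile(
                    series, day, lat, lon, dcm_cutoff=dcm_table.cutoff(lat), **kwargs
                )
            )
        except (InsufficientDataError, AllDarkError):
            continue
    return out


def qc_profile(
    profile: AttenuationProfile,
    min_bins: int = 10,
    max_negative_fraction: float = 0.5,
    max_jump: float = 0.1,
    surface_exclude_m: float = 20.0,
) -> AttenuationProfile:
    """Apply quality control; failure is a state (qc_pass=False), not an error.

    Surface-anomaly bins above ``surface_exclude_m`` are removed; the
    profile then must have enough defined bins, a bounded fraction of
    negative-k bins (negatives are retained, not clipped), and no
    single-bin jump larger than ``max_jump``.
    """
    keep = profile.depth_bins >= surface_exclude_m
    prof = replace(
        profile,
        depth_bins=profile.depth_bins[keep],
        k=profile.k[keep],
        n_obs=profile.n_obs[keep],
    )
    flags = {"surface_bins_removed": int((~keep).sum())}
    flags["enough_bins"] = prof.k.size >= min_bins
    flags["negative_fraction_ok"] = (
        prof.k.size > 0 and prof.negative_fraction <= max_negative_fraction
    )
    jumps = np.abs(np.diff(prof.k)) if prof.k.size > 1 else np.array([0.0])
    flags["max_jump_ok"] = bool(jumps.max() <= max_jump) if jumps.size else True
    prof.qc_pass = bool(
        flags["enough_bins"] and flags["negative_fraction_ok"] and flags["max_jump_ok"]
    )
    prof.qc_flags = flags
    return prof


def _rolling_median(x: np.ndarray, size: int = 3) -> np.ndarray:
    if x.size < size:
        return x.copy()
    out = x.copy()
    h = size // 2
    for i in range(h, x.size - h):
        out[i] = np.median(x[i - h : i + h + 1])
    return out


def detect_scattering_overlap(
    profile: AttenuationProfile,
    margin: float = 0.25,
    min_run: int = 2,
    smooth_size: int = 3,
) -> DetectionResult:
    """Detect marked attenuation increases below the DCM cutoff.

    The reference is the within-profile minimum (median-smoothed) k at or
    below ``dcm_cutoff - bin_width``; overlap requires at least ``min_run``
    consecutive bins below the cutoff with k >= reference * (1 + margin).
    Preconditions (QC pass, profile extending below the cutoff) failing
    yields a not-evaluated result, distinct from overlap=False.
    """
    if not profile.qc_pass or not profile.extends_below_cutoff:
        return DetectionResult(overlap=None)
    z = profile.depth_bins
    ks = _rolling_median(profile.k, smooth_size)
    ref_zone = z >= profile.dcm_cutoff - profile.bin_width
    if not ref_zone.any():
        return DetectionResult(overlap=None)
    ref = float(ks[ref_zone].min())

    # a bin marks an increase only relative to the clearest water at or
    # above it (running minimum within the reference zone), so a profile
    # that merely keeps decreasing with depth can never qualify
    run_min = np.full(z.size, np.inf)
    current = np.inf
    for i in np.flatnonzero(ref_zone):
        current = min(current, ks[i])
        run_min[i] = current
    run_min = np.maximum(run_min, 1e-4)  # negative/zero floor for the margin

    deep = np.flatnonzero(z > profile.dcm_cutoff)
    qualifying = ks[deep] >= run_min[deep] * (1.0 + margin)
    peaks: list[float] = []
    peak_excess = 0.0
    i = 0
    while i < qualifying.size:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < qualifying.size and qualifying[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            run = deep[i : j + 1]
            best = run[np.argmax(ks[run])]
            peaks.append(float(z[best]))
            peak_excess = max(
                peak_excess, float((ks[run] / run_min[run]).max() - 1.0)
            )
        i = j + 1
    return DetectionResult(
        overlap=bool(peaks),
        reference_min_k=ref,
        peak_depths=tuple(peaks),
        peak_excess=peak_excess if peaks else None,
    )


def cluster_profiles(
    profiles: list[AttenuationProfile],
    k_clusters: int,
    seed: int = 0,
) -> list[ProfileCluster]:
    """Partition same-biome profiles on a common bin grid; composite each.

    Profiles are snapped to a regular grid at the bin width; missing grid
    values are mean-imputed per bin for clustering (composites use only the
    observed values). Clusters are ordered by mean k over depths <= 100 m.
    """
    if len(profiles) < k_clusters:
        raise InsufficientDataError(
            f"need >= {k_clusters} profiles, got {len(profiles)}"
        )
    bw = profiles[0].bin_width
    lo = min(p.depth_bins.min() for p in profiles)
    hi = max(p.depth_bins.max() for p in profiles)
    grid = np.arange(np.floor(lo / bw) * bw, np.ceil(hi / bw) * bw + bw / 2, bw)

    mat = np.full((len(profiles), grid.size), np.nan)
    for i, p in enumerate(profiles):
        idx = np.rint((p.depth_bins - grid[0]) / bw).astype(int)
        ok = (idx >= 0) & (idx < grid.size)
        mat[i, idx[ok]] = p.k[ok]

    col_ok = ~np.all(np.isnan(mat), axis=0)
    grid = grid[col_ok]
    mat = mat[:, col_ok]
    col_mean = np.nanmean(mat, axis=0)
    filled = np.where(np.isnan(mat), col_mean, mat)
    mu = filled.mean(axis=0)
    sd = filled.std(axis=0)
    sd[sd == 0] = 1.0
    z = (filled - mu) / sd
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed).fit(z)

    clusters: list[ProfileCluster] = []
    for c in range(k_clusters):
        members = np.flatnonzero(km.labels_ == c)
        sub = mat[members]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=0)
            n = np.sum(~np.isnan(sub), axis=0)
            sdv = np.nanstd(sub, axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
        ci = 1.96 * np.where(n > 0, sdv / np.sqrt(np.maximum(n, 1)), np.nan)
        shallow = grid <= 100.0
        shallow_mean = float(np.nanmean(mean[shallow])) if shallow.any() else np.nan
        clusters.append(
            ProfileCluster(
                cluster_id=c,
                members=list(map(int, members)),
                depth_grid=grid,
                composite_mean=mean,
                composite_ci95=ci,
                shallow_mean_k=shallow_mean,
            )
        )
    clusters.sort(key=lambda cl: cl.shallow_mean_k)
    for i, cl in enumerate(clusters):
        cl.cluster_id = i
    return clusters


def profiles_to_frame(profiles: list[AttenuationProfile]) -> pd.DataFrame:
    """Long-format table: fish_id,date,depth_bin_m,k_per_m,n_obs,qc."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": p.fish_id,
                    "date": p.date,
                    "depth_bin_m": p.depth_bins,
                    "k_per_m": p.k,
                    "n_obs": p.n_obs,
                    "qc": p.qc_pass,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
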