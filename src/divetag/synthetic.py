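"""Synthetic ocean scenarios and archival-tag record simulation.

Generates depth / temperature / light time series, daily track positions,
and gridded backscatter fields from a fully specified ground truth, so
every downstream stage of the pipeline can be tested without real tags.

The attenuation field is a sum of a constant background, a Gaussian deep
chlorophyll maximum (DCM), and Gaussian scattering layers whose centers may
migrate sinusoidally between a midnight (shallow) and noon (deep) depth.
Light at depth is surface ln-irradiance (diel half-sine between sunrise and
sunset) minus the depth-integrated attenuation, floored at a sensor floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.special import erf

from divetag import solar

__all__ = [
    "AttenuationComponent",
    "OceanScenario",
    "BehaviorConfig",
    "ScheduledDive",
    "TagSeries",
    "ScenarioError",
    "build_scenario",
    "simulate_tag_series",
    "simulate_backscatter",
    "match_dives_to_truth",
]

_SQRT2 = np.sqrt(2.0)


class ScenarioError(ValueError):
    """Invalid scenario/behavior parameter; message names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class AttenuationComponent:
    """One additive term of the attenuation field K(z, t).

    kind 'background' uses ``k0`` (constant in depth and time); kinds 'dcm'
    and 'scattering_layer' are Gaussians in depth with amplitude ``peak_k``.
    A scattering layer may carry a diel migration (noon deep, midnight
    shallow); its center is interpolated sinusoidally over the local day.
    """

    kind: str
    k0: float | None = None
    peak_k: float | None = None
    center_depth: float | None = None
    width: float | None = None
    noon_depth: float | None = None
    midnight_depth: float | None = None

    @property
    def migrates(self) -> bool:
        return self.noon_depth is not None and self.midnight_depth is not None

    def center_at(self, local_hour):
        """Layer center depth (m) at a local solar hour (scalar or array)."""
        if not self.migrates:
            return np.broadcast_to(
                np.float64(self.center_depth), np.shape(local_hour)
            ) if np.ndim(local_hour) else float(self.center_depth)
        # shallowest at local midnight, deepest at local noon
        frac = (1.0 - np.cos(2.0 * np.pi * np.asarray(local_hour) / 24.0)) / 2.0
        out = self.midnight_depth + (self.noon_depth - self.midnight_depth) * frac
        return float(out) if np.ndim(local_hour) == 0 else out


def _validate_component(i: int, c: AttenuationComponent) -> None:
    prefix = f"attenuation[{i}]"
    if c.kind == "background":
        if c.k0 is None or c.k0 <= 0:
            raise ScenarioError(f"{prefix}.k0", "background k0 must be > 0")
        return
    if c.kind not in ("dcm", "scattering_layer"):
        raise ScenarioError(f"{prefix}.kind", f"unknown kind {c.kind!r}")
    if c.peak_k is None or c.peak_k <= 0:
        raise ScenarioError(f"{prefix}.peak_k", "peak_k must be > 0")
    if c.width is None or c.width <= 0:
        raise ScenarioError(f"{prefix}.width", "width must be > 0")
    if c.migrates:
        if c.noon_depth < c.midnight_depth:
            raise ScenarioError(
                f"{prefix}.noon_depth",
                "migrant layers must have noon_depth >= midnight_depth",
            )
    elif c.center_depth is None or c.center_depth < 0:
        raise ScenarioError(f"{prefix}.center_depth", "center_depth must be >= 0")


@dataclass(frozen=True)
class OceanScenario:
    """Ground-truth environment: temperature structure + attenuation field."""

    surface_temp: float
    deep_temp: float
    mld_true: float
    thermocline_width: float
    components: tuple[AttenuationComponent, ...]
    latitude: float
    longitude: float
    surface_noon_log: float = 14.0  # ln-irradiance at solar noon, surface
    light_floor: float = -10.0  # sensor floor, ln units

    def __post_init__(self):
        if self.surface_temp < self.deep_temp:
            raise ScenarioError("surface_temp", "must be >= deep_temp")
        if self.mld_true <= 0:
            raise ScenarioError("mld_true", "must be > 0")
        if self.thermocline_width <= 0:
            raise ScenarioError("thermocline_width", "must be > 0")
        if not any(c.kind == "background" for c in self.components):
            raise ScenarioError("attenuation", "a background component is required")
        for i, c in enumerate(self.components):
            _validate_component(i, c)

    # -- temperature -------------------------------------------------------
    def temperature(self, depth):
        """Two-layer tanh profile: monotone non-increasing with depth."""
        z = np.asarray(depth, dtype=float)
        t = self.deep_temp + (self.surface_temp - self.deep_temp) * 0.5 * (
            1.0 - np.tanh((z - self.mld_true) / self.thermocline_width)
        )
        return float(t) if np.ndim(depth) == 0 else t

    # -- attenuation -------------------------------------------------------
    def attenuation(self, depth, local_hour=12.0):
        """K(z, t) in 1/m at a local solar hour."""
        z = np.asarray(depth, dtype=float)
        k = np.zeros_like(z)
        for c in self.components:
            if c.kind == "background":
                k = k + c.k0
            else:
                center = c.center_at(local_hour)
                k = k + c.peak_k * np.exp(-((z - center) ** 2) / (2.0 * c.width**2))
        return float(k) if np.ndim(depth) == 0 else k

    def integrated_attenuation(self, depth, local_hour=12.0):
        """Optical depth: integral of K from the surface to ``depth``."""
        z = np.asarray(depth, dtype=float)
        tau = np.zeros_like(z)
        for c in self.components:
            if c.kind == "background":
                tau = tau + c.k0 * z
            else:
                center = c.center_at(local_hour)
                w = c.width
                tau = tau + c.peak_k * w * np.sqrt(np.pi / 2.0) * (
                    erf((z - center) / (w * _SQRT2)) + erf(center / (w * _SQRT2))
                )
        return float(tau) if np.ndim(depth) == 0 else tau

    # -- light -------------------------------------------------------------
    def surface_log_irradiance(self, times: np.ndarray, day: _date) -> np.ndarray:
        """Diel half-sine of surface ln-irradiance; floor at night.

        ``times`` are seconds since UTC midnight of ``day``.
        """
        ev = solar.solar_events(day, self.latitude, self.longitude)
        midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
        sr = (ev.sunrise - midnight).total_seconds()
        ss = (ev.sunset - midnight).total_seconds()
        t = np.asarray(times, dtype=float)
        frac = np.clip((t - sr) / (ss - sr), 0.0, 1.0)
        amp = self.surface_noon_log - self.light_floor
        out = self.light_floor + amp * np.sin(np.pi * frac)
        out[(t < sr) | (t > ss)] = self.light_floor
        return out

    def log_irradiance(self, depth, times, day: _date) -> np.ndarray:
        """ln-irradiance at depth, floored at the sensor floor."""
        t = np.asarray(times, dtype=float)
        local_hour = (t / 3600.0 + solar.normalize_lon(self.longitude) / 15.0) % 24.0
        surf = self.surface_log_irradiance(t, day)
        li = surf - self.integrated_attenuation(depth, local_hour)
        return np.maximum(li, self.light_floor)


def build_scenario(config: dict) -> OceanScenario:
    """Build and validate an :class:`OceanScenario` from a plain dict.

    Raises :class:`ScenarioError` naming the offending field.
    """
    comps = []
    for c in config.get("attenuation", []):
        c = dict(c)
        mig = c.pop("diel_migration", None) or {}
        comps.append(
            AttenuationComponent(
                kind=c.get("kind", ""),
                k0=c.get("k0"),
                peak_k=c.get("peak_k"),
                center_depth=c.get("center_depth"),
                width=c.get("width"),
                noon_depth=mig.get("noon_depth"),
                midnight_depth=mig.get("midnight_depth"),
            )
        )
    required = ("surface_temp", "deep_temp", "mld_true", "thermocline_width",
                "latitude", "longitude")
    for name in required:
        if name not in config:
            raise ScenarioError(name, "missing required scenario parameter")
    return OceanScenario(
        surface_temp=float(config["surface_temp"]),
        deep_temp=float(config["deep_temp"]),
        mld_true=float(config["mld_true"]),
        thermocline_width=float(config["thermocline_width"]),
        components=tuple(comps),
        latitude=float(config["latitude"]),
        longitude=float(config["longitude"]),
        surface_noon_log=float(config.get("surface_noon_log", 14.0)),
        light_floor=float(config.get("light_floor", -10.0)),
    )


@dataclass
class BehaviorConfig:
    """Dive scheduling and sensor-noise parameters for the simulator.

    Dive counts are exact per-day counts (not Poisson means); dives are
    scheduled in shuffled, evenly spaced slots between sunrise and sunset.
    """

    n_days: int = 3
    u_dives_per_day: int = 3
    v_dives_per_day: int = 3
    u_target_layer: int = 1  # index into scenario.components
    u_bottom_duration_min: tuple[float, float] = (20.0, 4.0)
    v_apex_depth: tuple[float, float] = (250.0, 30.0)
    descent_rate: tuple[float, float] = (1.0, 0.1)  # m/s
    ascent_rate: tuple[float, float] = (0.9, 0.1)  # m/s
    surface_depth: tuple[float, float] = (15.0, 4.0)
    sampling_interval_s: int = 60
    depth_sd: float = 0.5
    temp_sd: float = 0.05
    light_sd: float = 0.02
    seed: int = 0
    start_date: _date = field(default_factory=lambda: _date(2019, 6, 15))
    fish_length: float = 0.8  # m
    wiggle_amplitude: float = 2.0  # m, bottom-phase oscillation
    lon_drift_per_day: float = 0.0
    # midday profiling excursion: continuous sawtooth through the water
    # column around solar noon, giving the attenuation profiler dense
    # depth-bin occupancy (regular dives are scheduled around the block)
    profiling_excursion: bool = False
    profiling_depth: float = 320.0
    profiling_rate: float = 0.5  # m/s
    profiling_halfwidth_h: float = 1.2

    def __post_init__(self):
        if self.sampling_interval_s not in (30, 60):
            raise ScenarioError("sampling_interval_s", "must be 30 or 60")
        for name in ("descent_rate", "ascent_rate"):
            if getattr(self, name)[0] <= 0:
                raise ScenarioError(name, "mean rate must be > 0")
        if self.n_days < 1:
            raise ScenarioError("n_days", "must be >= 1")
        if self.fish_length <= 0:
            raise ScenarioError("fish_length", "must be > 0")


@dataclass(frozen=True)
class ScheduledDive:
    """Ground-truth record of one scheduled dive."""

    label: str  # 'U' or 'V'
    start: datetime
    end: datetime
    target_depth: float
    bottom_duration_min: float
    truncated: bool


@dataclass
class TagSeries:
    """One simulated (or loaded) archival record plus daily positions."""

    data: pd.DataFrame  # columns: timestamp, depth_m, temp_c, light
    positions: pd.DataFrame  # columns: date, lat, lon
    fish_length: float
    fish_id: str = "fish0"
    light_channel: str = "log"  # 'log' (ln-irradiance) or 'linear'
    truth: list[ScheduledDive] = field(default_factory=list)

    @property
    def sampling_interval_s(self) -> float:
        ts = self.data["timestamp"]
        return float((ts.iloc[1] - ts.iloc[0]).total_seconds())

    def day(self, day: _date) -> pd.DataFrame:
        mask = self.data["timestamp"].dt.date == day
        return self.data.loc[mask]

    def position_on(self, day: _date) -> tuple[float, float]:
        row = self.positions.loc[self.positions["date"] == day]
        if row.empty:
            raise KeyError(f"no position for {day}")
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])


def _positive_normal(rng, mean, sd, floor=1e-3):
    return max(floor, float(rng.normal(mean, sd)))


def _plan_day(
    scenario: OceanScenario,
    behavior: BehaviorConfig,
    day: _date,
    lat: float,
    lon: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[float, float]], list[ScheduledDive]]:
    """Control points (sec-of-day, depth) and truth records for one day."""
    ev = solar.solar_events(day, lat, lon)
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    sr = (ev.sunrise - midnight).total_seconds()
    ss = (ev.sunset - midnight).total_seconds()
    noon = (ev.solar_noon - midnight).total_seconds()
    # the solar day may run past UTC midnight; keep all activity within the
    # simulated calendar day so no scheduled dive falls off the sample grid
    day_end = 86400.0 - behavior.sampling_interval_s
    window0 = max(sr, 0.0) + 900.0
    window1 = min(ss, day_end) - 900.0

    labels = ["U"] * behavior.u_dives_per_day + ["V"] * behavior.v_dives_per_day
    n = len(labels)
    points: list[tuple[float, float]] = []
    truth: list[ScheduledDive] = []

    def surf():
        return max(0.5, float(rng.normal(*behavior.surface_depth)))

    # midday sawtooth block for attenuation profiling
    block: tuple[float, float] | None = None

    # mixed-layer wander between dives: a control point every 10 minutes
    # (never inside the profiling block)
    def add_surface(t0, t1):
        t = t0
        while t < t1:
            if not (block and block[0] - 60.0 <= t <= block[1] + 60.0):
                points.append((t, surf()))
            t += 600.0

    if behavior.profiling_excursion:
        hw = behavior.profiling_halfwidth_h * 3600.0
        b0 = max(window0, noon - hw)
        b1 = min(window1, noon + hw)
        block = (b0, b1)
        z_top = 20.0
        leg = (behavior.profiling_depth - z_top) / behavior.profiling_rate
        t, going_down = b0, True
        points.append((b0 - 60.0, surf()))
        while t < b1:
            points.append((t, z_top if going_down else behavior.profiling_depth))
            t += leg
            going_down = not going_down
        points.append((b1, z_top))
        points.append((b1 + 60.0, surf()))

    if n == 0:
        add_surface(0.0, block[0] - 60.0 if block else 86400.0)
        if block:
            add_surface(block[1] + 60.0, 86400.0)
        return points, truth

    # dive slots: evenly spaced within the daytime window, skipping the
    # profiling block (dives allocated to sub-windows by their length)
    if block and block[1] > block[0]:
        subs = [(window0, block[0] - 60.0), (block[1] + 60.0, window1)]
        subs = [(a, b) for a, b in subs if b - a > 600.0]
    else:
        subs = [(window0, window1)]
    total_len = sum(b - a for a, b in subs)
    starts: list[float] = []
    remaining = n
    for j, (a, b) in enumerate(subs):
        nj = remaining if j == len(subs) - 1 else round(n * (b - a) / total_len)
        nj = min(nj, remaining)
        slot = (b - a) / max(nj, 1)
        starts.extend(a + i * slot for i in range(nj))
        remaining -= nj
    starts.sort()

    order = rng.permutation(n)
    add_surface(0.0, window0)
    cursor = window0
    for i in range(n):
        label = labels[order[i]]
        t_start = starts[i]
        add_surface(cursor, t_start)
        z0 = surf()
        d_rate = _positive_normal(rng, *behavior.descent_rate)
        a_rate = _positive_normal(rng, *behavior.ascent_rate)
        if label == "U":
            comp = scenario.components[behavior.u_target_layer]
            bottom_s = max(60.0, rng.normal(*behavior.u_bottom_duration_min) * 60.0)
        else:
            bottom_s = 0.0

        limit = min(ss, day_end)
        truncated = False
        while True:
            if label == "U":
                mid_guess = t_start + 600.0
                target = float(
                    comp.center_at(
                        (mid_guess / 3600.0 + solar.normalize_lon(lon) / 15.0) % 24.0
                    )
                )
            else:
                target = max(
                    scenario.mld_true + 30.0, float(rng.normal(*behavior.v_apex_depth))
                )
            t_desc = (target - z0) / d_rate
            t_asc = (target - z0) / a_rate
            t_end = t_start + t_desc + bottom_s + t_asc
            if t_end <= limit:
                break
            # cannot finish before sunset: truncate, never drop silently
            truncated = True
            if label == "U" and bottom_s > 60.0:
                bottom_s = max(60.0, bottom_s - (t_end - limit))
                continue
            scale = max(0.2, (limit - t_start) / (t_desc + bottom_s + t_asc))
            target = z0 + (target - z0) * scale
            t_desc = (target - z0) / d_rate
            t_asc = (target - z0) / a_rate
            t_end = t_start + t_desc + bottom_s + t_asc
            break

        points.append((t_start, z0))
        points.append((t_start + t_desc, target))
        if bottom_s > 0:
            # bottom-phase wiggle: control point every 2 minutes
            t = t_start + t_desc + 120.0
            j = 0
            while t < t_start + t_desc + bottom_s:
                wig = behavior.wiggle_amplitude * np.sin(j * 1.3)
                points.append((t, max(0.0, target + wig)))
                t += 120.0
                j += 1
            points.append((t_start + t_desc + bottom_s, target))
        points.append((t_end, surf()))
        truth.append(
            ScheduledDive(
                label=label,
                start=midnight + timedelta(seconds=t_start),
                end=midnight + timedelta(seconds=t_end),
                target_depth=float(target),
                bottom_duration_min=bottom_s / 60.0,
                truncated=truncated,
            )
        )
        cursor = t_end
    add_surface(cursor, 86400.0)
    return points, truth


def simulate_tag_series(
    scenario: OceanScenario, behavior: BehaviorConfig
) -> TagSeries:
    """Simulate one fish's archival record; bit-reproducible for a seed."""
    rng = np.random.default_rng(behavior.seed)
    dt = float(behavior.sampling_interval_s)
    frames = []
    positions = []
    truth: list[ScheduledDive] = []
    for d in range(behavior.n_days):
        day = behavior.start_date + timedelta(days=d)
        lat = scenario.latitude
        lon = (scenario.longitude + behavior.lon_drift_per_day * d) % 360.0
        positions.append({"date": day, "lat": lat, "lon": lon})
        pts, day_truth = _plan_day(scenario, behavior, day, lat, lon, rng)
        truth.extend(day_truth)
        pts = sorted(pts)
        t_ctrl = np.array([p[0] for p in pts])
        z_ctrl = np.array([p[1] for p in pts])
        t_grid = np.arange(0.0, 86400.0, dt)
        depth = np.interp(t_grid, t_ctrl, z_ctrl)
        depth_noisy = np.maximum(
            0.0, depth + rng.normal(0.0, behavior.depth_sd, depth.size)
        )
        temp = scenario.temperature(depth) + rng.normal(
            0.0, behavior.temp_sd, depth.size
        )
        li = scenario.log_irradiance(depth, t_grid, day) + rng.normal(
            0.0, behavior.light_sd, depth.size
        )
        midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
        ts = pd.to_datetime(midnight) + pd.to_timedelta(t_grid, unit="s")
        frames.append(
            pd.DataFrame(
                {"timestamp": ts, "depth_m": depth_noisy, "temp_c": temp, "light": li}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    pos = pd.DataFrame(positions)
    return TagSeries(
        data=data,
        positions=pos,
        fish_length=behavior.fish_length,
        truth=truth,
    )


def simulate_backscatter(
    scenario: OceanScenario,
    n_days: int,
    seed: int,
    depth_max: float = 600.0,
    bin_width: float = 10.0,
    noise_db: float = 1.0,
    base_db: float = -95.0,
    layer_gain_db: float = 35.0,
) -> pd.DataFrame:
    """Hourly backscatter profiles over a 0-``depth_max`` m grid.

    Returns a long-format frame with columns
    ``day, hour, depth_m, sv_db, lat, lon`` where ``hour`` is the local
    solar hour. Backscatter is a sum of layer Gaussians (in dB above a
    noise base) tracking each scattering layer's diel schedule.
    """
    if depth_max < 600.0:
        raise ScenarioError("depth_max", "grid must cover 0-600 m")
    rng = np.random.default_rng(seed)
    depths = np.arange(bin_width / 2.0, depth_max, bin_width)
    layers = [c for c in scenario.components if c.kind == "scattering_layer"]
    rows = []
    for day in range(n_days):
        for hour in range(24):
            signal = np.zeros_like(depths)
            for c in layers:
                center = float(c.center_at(float(hour)))
                signal += np.exp(-((depths - center) ** 2) / (2.0 * c.width**2))
            sv = base_db + layer_gain_db * signal + rng.normal(0, noise_db, depths.size)
            rows.append(
                pd.DataFrame(
                    {
                        "day": day,
                        "hour": hour,
                        "depth_m": depths,
                        "sv_db": sv,
                        "lat": scenario.latitude,
                        "lon": scenario.longitude,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def match_dives_to_truth(dives, truth: list[ScheduledDive]):
    """Pair extracted dives with scheduled ground-truth dives by time overlap.

    Returns a list of ``(dive, scheduled)`` pairs; a dive matches the truth
    record whose interval overlaps it the most (None if no overlap).
    """
    pairs = []
    for dv in dives:
        best, best_ov = None, 0.0
        for sch in truth:
            ov = (
                min(dv.end_time, sch.end) - max(dv.start_time, sch.start)
            ).total_seconds()
            if ov > best_ov:
                best, best_ov = sch, ov
        pairs.append((dv, best))
    return pairs
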