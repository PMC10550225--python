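"""Dive bioenergetics: metabolic-rate surrogate, cost integration,
hypothetical deeper dives, and cost-equivalent foraging durations.

The metabolic-rate model is a pluggable parametric surrogate

    MR(U, T) = (R0 + c * max(U, u_min)**p) * exp(beta * max(0, T_ref - T))

in mg O2 / kg / h, with swim speed U in body lengths per second and water
temperature T in degrees C. Metabolism is elevated in cold water (below
T_ref) and rises with speed. Speed is proxied by vertical rate only;
horizontal swimming is absorbed into the baseline R0. All parameters are
configuration; a tabulated response surface can replace the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from divetag.dives import Dive
from divetag.synthetic import TagSeries

__all__ = [
    "MetabolicModel",
    "DiveEnergetics",
    "HypotheticalComparison",
    "metabolic_rate",
    "dive_energetics",
    "observed_dive_params",
    "hypothetical_dive_comparison",
    "cost_equivalent_duration",
]


@dataclass(frozen=True)
class MetabolicModel:
    """Parametric total-metabolic-rate surface (mg O2 / kg / h)."""

    r0: float = 175.0  # baseline at T_ref, zero excess speed
    c: float = 70.0  # speed coefficient
    p: float = 2.0  # speed exponent
    beta: float = 0.035  # 1/degC cold-elevation rate
    t_ref: float = 18.0  # degC
    u_min: float = 0.8  # body lengths / s speed floor
    temp_range: tuple[float, float] = (0.0, 30.0)
    speed_range: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self):
        if self.r0 <= 0 or self.c < 0 or self.beta < 0 or self.u_min < 0:
            raise ValueError("model parameters must be non-negative with r0 > 0")


def metabolic_rate(speed, temp, model: MetabolicModel = MetabolicModel()):
    """MR(U, T) in mg O2/kg/h; inputs outside the valid range are clamped."""
    u = np.asarray(speed, dtype=float)
    t = np.asarray(temp, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite speed or temperature")
    u = np.clip(u, *model.speed_range)
    t = np.clip(t, *model.temp_range)
    ueff = np.maximum(u, model.u_min)
    mr = (model.r0 + model.c * ueff**model.p) * np.exp(
        model.beta * np.maximum(0.0, model.t_ref - t)
    )
    return float(mr) if np.ndim(speed) == 0 and np.ndim(temp) == 0 else mr


@dataclass(frozen=True)
class DiveEnergetics:
    dive_id: int
    cost: float  # mg O2 / kg, time integral of MR
    cost_rate: float  # mg O2 / kg / min
    profitability: float  # min * kg / mg O2 (bottom time per unit cost)
    bottom_duration: float  # minutes (carried for the identities)
    total_duration: float


def _vertical_speeds(depth: np.ndarray, dt_s: float, fish_length: float) -> np.ndarray:
    """Per-sample |vertical rate| in body lengths/s (central differences)."""
    z = np.asarray(depth, dtype=float)
    v = np.empty_like(z)
    v[1:-1] = np.abs(z[2:] - z[:-2]) / (2.0 * dt_s)
    v[0] = np.abs(z[1] - z[0]) / dt_s
    v[-1] = np.abs(z[-1] - z[-2]) / dt_s
    return v / fish_length


def dive_energetics(
    dive: Dive,
    series: TagSeries,
    model: MetabolicModel = MetabolicModel(),
    fish_length: float | None = None,
) -> DiveEnergetics:
    """Trapezoidal integral of MR over the dive on the native sampling grid."""
    if dive.total_duration is None or not dive.total_duration > 0:
        raise ValueError("zero-duration dive")
    if fish_length is None:
        fish_length = series.fish_length
    s, e = dive.samples
    depth = series.data["depth_m"].to_numpy(float)[s : e + 1]
    temp = series.data["temp_c"].to_numpy(float)[s : e + 1]
    dt_s = series.sampling_interval_s
    speed = _vertical_speeds(depth, dt_s, fish_length)
    mr = metabolic_rate(speed, temp, model)  # mg O2/kg/h
    # trapezoid over the grid plus half-sample end caps, so each sample
    # represents one full interval and cost_rate * total_duration == cost
    dx_h = dt_s / 3600.0
    cost = float(np.trapezoid(mr, dx=dx_h) + (mr[0] + mr[-1]) * dx_h / 2.0)
    cost_rate = cost / dive.total_duration
    return DiveEnergetics(
        dive_id=dive.dive_id,
        cost=cost,
        cost_rate=cost_rate,
        profitability=dive.bottom_duration / cost,
        bottom_duration=dive.bottom_duration,
        total_duration=dive.total_duration,
    )


def phase_costs(
    dive: Dive,
    series: TagSeries,
    model: MetabolicModel = MetabolicModel(),
    fish_length: float | None = None,
) -> dict[str, float]:
    """Per-phase costs; their sum equals the dive cost exactly."""
    if dive.bottom is None:
        raise ValueError("dive must be segmented")
    if fish_length is None:
        fish_length = series.fish_length
    s, e = dive.samples
    depth = series.data["depth_m"].to_numpy(float)[s : e + 1]
    temp = series.data["temp_c"].to_numpy(float)[s : e + 1]
    dt_s = series.sampling_interval_s
    mr = metabolic_rate(_vertical_speeds(depth, dt_s, fish_length), temp, model)
    dx_h = dt_s / 3600.0
    b0, b1 = dive.bottom[0] - s, dive.bottom[1] - s
    return {
        "descent": float(mr[:b0].sum() * dx_h),
        "bottom": float(mr[b0 : b1 + 1].sum() * dx_h),
        "ascent": float(mr[b1 + 1 :].sum() * dx_h),
    }


@dataclass(frozen=True)
class ObservedDiveParams:
    """Idealized geometry of an observed dive used for what-if comparisons."""

    start_depth: float  # m
    max_depth: float  # m
    descent_rate: float  # m/s
    ascent_rate: float  # m/s
    bottom_duration: float  # minutes
    bottom_speed: float  # BL/s during the bottom phase


def observed_dive_params(
    dive: Dive, series: TagSeries, fish_length: float | None = None
) -> ObservedDiveParams:
    """Extract the idealized parameters of a segmented dive."""
    if dive.bottom is None:
        raise ValueError("dive must be segmented")
    if fish_length is None:
        fish_length = series.fish_length
    s, e = dive.samples
    depth = series.data["depth_m"].to_numpy(float)
    dt_s = series.sampling_interval_s
    z0 = float(depth[s])
    d_rate = (
        (dive.max_depth - z0) / (dive.descent_duration * 60.0)
        if dive.descent_duration > 0
        else 1.0
    )
    a_rate = (
        (dive.max_depth - float(depth[e])) / (dive.ascent_duration * 60.0)
        if dive.ascent_duration > 0
        else 1.0
    )
    b0, b1 = dive.bottom
    bz = depth[b0 : b1 + 1]
    if bz.size > 1:
        bspeed = float(np.abs(np.diff(bz)).mean() / dt_s / fish_length)
    else:
        bspeed = 0.0
    return ObservedDiveParams(
        start_depth=z0,
        max_depth=dive.max_depth,
        descent_rate=max(d_rate, 1e-3),
        ascent_rate=max(a_rate, 1e-3),
        bottom_duration=dive.bottom_duration,
        bottom_speed=bspeed,
    )


@dataclass(frozen=True)
class HypotheticalComparison:
    observed_dive_id: int
    target_depth: float
    rate_ratio: float  # hypothetical cost_rate / observed (idealized) cost_rate
    cost_ratio: float
    equivalent_bottom_fraction: float | None  # None when infeasible
    infeasible: bool
    hypothetical_cost: float
    hypothetical_duration: float  # minutes
    baseline_cost: float


def _idealized_cost(
    params: ObservedDiveParams,
    depth: float,
    temp_profile: Callable[[float], float],
    model: MetabolicModel,
    fish_length: float,
    dz: float = 1.0,
) -> tuple[float, float, float, float]:
    """Cost of the idealized dive (descend, hold, ascend) to ``depth``.

    Returns (total cost mg O2/kg, duration min, travel cost, bottom MR/h).
    Travel legs integrate MR over depth on a ``dz`` grid; the bottom phase
    is at constant depth/temperature.
    """
    zgrid = np.arange(params.start_depth, depth + dz / 2.0, dz)
    if zgrid.size < 2:
        zgrid = np.array([params.start_depth, depth])
    tz = np.asarray([float(temp_profile(z)) for z in zgrid])
    if not np.all(np.isfinite(tz)):
        raise ValueError(f"temperature profile undefined above {depth} m")
    travel = 0.0
    travel_time_s = 0.0
    for rate in (params.descent_rate, params.ascent_rate):
        u = rate / fish_length
        mr = metabolic_rate(np.full(zgrid.size, u), tz, model)  # mg O2/kg/h
        # dt = dz / rate seconds per meter
        travel += float(np.trapezoid(mr, zgrid)) / rate / 3600.0
        travel_time_s += (depth - params.start_depth) / rate
    t_bottom = float(temp_profile(depth))
    mr_bottom = metabolic_rate(params.bottom_speed, t_bottom, model)
    bottom_cost = mr_bottom * params.bottom_duration / 60.0
    total = travel + bottom_cost
    duration_min = travel_time_s / 60.0 + params.bottom_duration
    return total, duration_min, travel, mr_bottom


def hypothetical_dive_comparison(
    observed: ObservedDiveParams,
    target_depth: float,
    temp_profile: Callable[[float], float],
    model: MetabolicModel = MetabolicModel(),
    fish_length: float = 0.8,
    observed_dive_id: int = -1,
) -> HypotheticalComparison:
    """Contrast a hypothetical deeper dive against the observed geometry.

    The hypothetical dive keeps the observed descent/ascent rates and
    bottom duration but extends travel to ``target_depth``, taking its
    temperatures from ``temp_profile``. Both dives are costed through the
    same idealized integrator, so the identity case (target equal to the
    observed max depth) yields ratios of exactly 1.
    """
    if target_depth < observed.max_depth:
        raise ValueError("target_depth must be >= observed max_depth")
    base_cost, base_dur, _, _ = _idealized_cost(
        observed, observed.max_depth, temp_profile, model, fish_length
    )
    hyp_cost, hyp_dur, hyp_travel, hyp_mr_bottom = _idealized_cost(
        observed, target_depth, temp_profile, model, fish_length
    )
    cost_ratio = hyp_cost / base_cost
    rate_ratio = (hyp_cost / hyp_dur) / (base_cost / base_dur)
    frac, infeasible = cost_equivalent_duration(
        base_cost, hyp_travel, hyp_mr_bottom, observed.bottom_duration
    )
    return HypotheticalComparison(
        observed_dive_id=observed_dive_id,
        target_depth=target_depth,
        rate_ratio=rate_ratio,
        cost_ratio=cost_ratio,
        equivalent_bottom_fraction=frac,
        infeasible=infeasible,
        hypothetical_cost=hyp_cost,
        hypothetical_duration=hyp_dur,
        baseline_cost=base_cost,
    )


def cost_equivalent_duration(
    observed_cost: float,
    hypothetical_travel_cost: float,
    hypothetical_bottom_mr: float,
    observed_bottom_duration: float,
) -> tuple[float | None, bool]:
    """Bottom duration making the hypothetical dive cost-equivalent.

    Solves travel_cost + MR_bottom * b' = observed_cost for b' (minutes)
    and returns (b'/observed_bottom_duration, infeasible). If the travel
    cost alone exceeds the observed cost no positive b' exists — the dive
    cannot be made cost-equivalent by shortening its bottom phase.
    """
    if observed_bottom_duration <= 0:
        raise ValueError("observed bottom duration must be > 0")
    b_prime = (observed_cost - hypothetical_travel_cost) / hypothetical_bottom_mr * 60.0
    if b_prime <= 0:
        return None, True
    return min(b_prime / observed_bottom_duration, 1.0), False
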