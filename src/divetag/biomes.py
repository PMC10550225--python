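"""Province assignment, biome summaries, power fits, and IDW fields."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ProvinceBox",
    "ProvinceMap",
    "DEFAULT_PROVINCES",
    "PowerFit",
    "assign_province",
    "summarize_by_biome",
    "percent_change",
    "fit_costrate_power",
    "idw_field",
]


@dataclass(frozen=True)
class ProvinceBox:
    name: str
    lat_min: float
    lat_max: float
    lon_min: float  # degE in [0, 360)
    lon_max: float

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat_min <= lat <= self.lat_max
            and self.lon_min <= lon <= self.lon_max
        )


@dataclass(frozen=True)
class ProvinceMap:
    """Ordered province boxes; first match wins, else 'unassigned'."""

    provinces: tuple[ProvinceBox, ...]

    def assign(self, lat: float, lon: float) -> str:
        lon = float(lon) % 360.0
        for box in self.provinces:
            if box.contains(lat, lon):
                return box.name
        return "unassigned"


DEFAULT_PROVINCES = ProvinceMap(
    provinces=(
        ProvinceBox("North Central Pacific", 26.0, 40.0, 200.0, 220.0),
        ProvinceBox("northern California Current", 41.0, 49.0, 228.0, 235.0),
        ProvinceBox("southern California Current", 25.0, 33.0, 239.0, 246.0),
    )
)


def assign_province(lat: float, lon: float, pmap: ProvinceMap = DEFAULT_PROVINCES) -> str:
    return pmap.assign(lat, lon)


def summarize_by_biome(
    table: pd.DataFrame,
    province_col: str = "province",
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Per-province mean/sd/n for each metric column.

    Returns a frame indexed by province with columns
    ``(metric, 'mean'|'sd'|'n')``. Empty provinces simply do not appear.
    """
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c != province_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    g = table.groupby(province_col)[metrics]
    out = g.agg(["mean", "std", "count"])
    out.columns = pd.MultiIndex.from_tuples(
        [(m, {"std": "sd", "count": "n"}.get(s, s)) for m, s in out.columns]
    )
    return out


def percent_change(m1: float, m2: float) -> float:
    """Percent change from province 1 to province 2: 100 * (m2 - m1) / m1."""
    if m1 == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return 100.0 * (m2 - m1) / m1


@dataclass(frozen=True)
class PowerFit:
    """cost_rate = a * min_temp ** b, fit by OLS on the log-log scale."""

    a: float
    b: float
    fit_method: str
    se_b: float

    @property
    def sensitivity_linear_pct(self) -> float:
        """Linearized % change in cost rate per 10% increase in temperature."""
        return self.b * 10.0

    @property
    def sensitivity_exact_pct(self) -> float:
        return (1.1**self.b - 1.0) * 100.0


def fit_costrate_power(
    min_temp: np.ndarray, cost_rate: np.ndarray, method: str = "ols_loglog"
) -> PowerFit:
    """Fit the cost-rate-vs-minimum-temperature power function.

    Default is ordinary least squares of ln(cost_rate) on ln(min_temp);
    ``method='nls'`` refines with nonlinear least squares from the OLS
    start. Non-positive inputs are rejected with their indices.
    """
    t = np.asarray(min_temp, dtype=float)
    r = np.asarray(cost_rate, dtype=float)
    if t.size != r.size:
        raise ValueError("min_temp and cost_rate must be the same length")
    if t.size < 10:
        raise ValueError(f"need >= 10 pairs, got {t.size}")
    bad = np.flatnonzero((t <= 0) | (r <= 0) | ~np.isfinite(t) | ~np.isfinite(r))
    if bad.size:
        raise ValueError(f"non-positive or non-finite values at indices {bad.tolist()}")
    x = sm.add_constant(np.log(t))
    fit = sm.OLS(np.log(r), x).fit()
    a = float(np.exp(fit.params[0]))
    b = float(fit.params[1])
    se_b = float(fit.bse[1])
    if method == "nls":
        from scipy.optimize import curve_fit

        popt, pcov = curve_fit(lambda tt, aa, bb: aa * tt**bb, t, r, p0=[a, b])
        a, b = float(popt[0]), float(popt[1])
        se_b = float(np.sqrt(pcov[1, 1]))
    elif method != "ols_loglog":
        raise ValueError(f"unknown fit method {method!r}")
    return PowerFit(a=a, b=b, fit_method=method, se_b=se_b)


_EARTH_R_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance in km (broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * _EARTH_R_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw_field(
    samples: pd.DataFrame,
    grid_lat: np.ndarray,
    grid_lon: np.ndarray,
    power_exponent: float = 2.0,
    value_col: str = "value",
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on a lat x lon grid.

    ``samples`` has columns lat, lon, ``value_col``. Weights are
    great-circle distance to the ``-power_exponent``; a grid node coincident
    with a sample takes that sample's value exactly. Returns an array of
    shape (len(grid_lat), len(grid_lon)).
    """
    if samples.empty:
        raise ValueError("no samples")
    slat = samples["lat"].to_numpy(float)
    slon = samples["lon"].to_numpy(float)
    vals = samples[value_col].to_numpy(float)
    out = np.empty((len(grid_lat), len(grid_lon)))
    for i, gla in enumerate(np.asarray(grid_lat, dtype=float)):
        d = great_circle_km(gla, np.asarray(grid_lon, float)[:, None], slat, slon)
        hit = d < 1e-9
        w = 1.0 / np.maximum(d, 1e-12) ** power_exponent
        est = (w * vals).sum(axis=1) / w.sum(axis=1)
        rows_hit = hit.any(axis=1)
        if rows_hit.any():
            first = np.argmax(hit[rows_hit], axis=1)
            est[rows_hit] = vals[first]
        out[i] = est
    return out
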