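"""Trip-level behavioural summaries.

Two-dimensional kernel densities of dive statistics, cumulative PDI
distributions, LOESS day-of-trip trends with bootstrap bands, and the
trip-report table combining diving, movement, foraging and morphometric
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import bioenergetics as be
from .geo import Track, trip_distances
from .morphometrics import (MorphometryRecord, adipose_from_cones,
                            composition_split, mass_correction_breed)
from .tdr import DiveTable, extended_surface_intervals

__all__ = [
    "TripSummary",
    "trip_summary",
    "kde2d",
    "cumulative_pdi_curve",
    "trend_smooth",
]


@dataclass
class TripSummary:
    """Table-style trip report (grand means are mean ± SD over dives)."""

    trip_days: float
    n_dives: int
    n_pdi_gt_4min: int
    total_distance_km: float
    max_distance_km: float
    mass_gain_kg: float | None = None
    energy_gain_MJ: float | None = None
    events_per_day_mean: float | None = None
    dive_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "dive_metrics"}
        for (metric, split), row in self.dive_metrics.iterrows():
            d[f"{metric}_{split}"] = (row["mean"], row["sd"])
        return d


def _grand_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of the dive statistics, overall and split day/night.

    Only located dives (day/night known) enter the day and night splits.
    """
    metrics = {
        "max_depth_m": "depth_m", "duration_min": "duration_min",
        "bottom_time_min": "bottom_time_min",
        "descent_rate_ms": "descent_rate_ms", "ascent_rate_ms": "ascent_rate_ms",
        "pdi_min": "pdi_min",
    }
    located = df[df["is_day"].notna()]
    rows = {}
    for col, name in metrics.items():
        subsets = {
            "all": df[col],
            "day": located.loc[located["is_day"] == True, col],     # noqa: E712
            "night": located.loc[located["is_day"] == False, col],  # noqa: E712
        }
        for split, s in subsets.items():
            s = pd.to_numeric(s, errors="coerce").dropna()
            rows[(name, split)] = {
                "mean": float(s.mean()) if len(s) else np.nan,
                "sd": float(s.std(ddof=1)) if len(s) > 1 else np.nan,
                "n": len(s),
            }
    return pd.DataFrame(rows).T


def trip_summary(dives: DiveTable, track: Track | None = None,
                 morpho_pair: tuple | None = None, events=None,
                 colony_latlon=None, pdi_threshold_min: float = 4.0,
                 calibration=(1.0, 0.0)) -> TripSummary:
    """Assemble the trip report from the processed stages.

    ``dives`` is required; track, morphometry pair and jaw events each enable
    their block of metrics. Mass gain corrects both measured masses for
    onshore fasting days; energy gain applies tissue energetics to the change
    in adipose and lean mass between departure and arrival.
    """
    if len(dives) == 0:
        raise ValueError("missing stage input: dive table is empty")
    df = dives.df
    span_days = (df["end_time"].iloc[-1] - df["start_time"].iloc[0]) / 86400.0
    n_ext, _ = extended_surface_intervals(dives, pdi_threshold_min)

    total_km = max_km = np.nan
    if track is not None:
        if colony_latlon is None:
            colony_latlon = (track.lat[0], track.lon[0])
        total_km, max_km = trip_distances(track, colony_latlon)

    mass_gain = energy_gain = None
    if morpho_pair is not None:
        dep, arr = morpho_pair
        dep_mass = dep.mass_kg + mass_correction_breed(dep.mass_kg, dep.fasting_days)
        arr_mass = arr.mass_kg + mass_correction_breed(arr.mass_kg, arr.fasting_days)
        mass_gain = arr_mass - dep_mass
        f_dep = adipose_from_cones(dep, calibration)
        f_arr = adipose_from_cones(arr, calibration)
        *_, ad_dep, ffm_dep = composition_split(dep_mass, min(f_dep, 1.0))
        *_, ad_arr, ffm_arr = composition_split(arr_mass, min(f_arr, 1.0))
        lean_d, lipid_d = ffm_arr - ffm_dep, ad_arr - ad_dep
        c = be.EnergyConstants()
        energy_gain = be.round_half_up(
            lean_d * c.lean_dry_fraction * c.lean_energy_density
            + lipid_d * c.lipid_dry_fraction * c.lipid_energy_density, 1)

    ev_mean = None
    if events is not None:
        events = np.asarray(events, dtype=float)
        ev_mean = float(len(events) / span_days) if span_days > 0 else 0.0

    return TripSummary(
        trip_days=float(span_days), n_dives=len(df), n_pdi_gt_4min=n_ext,
        total_distance_km=total_km, max_distance_km=max_km,
        mass_gain_kg=mass_gain, energy_gain_MJ=energy_gain,
        events_per_day_mean=ev_mean, dive_metrics=_grand_means(df),
    )


def scott_bandwidth(x: np.ndarray) -> float:
    """Scott's rule for one axis of a 2-D Gaussian product kernel."""
    return float(np.std(x, ddof=1) * len(x) ** (-1.0 / 6.0))


def kde2d(x, y, bandwidth=None, gridsize: int = 64, extent=None):
    """2-D kernel density on a regular grid with a Gaussian product kernel.

    ``bandwidth`` is (bx, by); default is Scott's rule per axis. Returns
    (xg, yg, density) where density[i, j] is at (xg[j], yg[i]) and integrates
    to ~1 over the grid (within 1% when the extent covers the data, which the
    default 3-bandwidth padding does).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) axis")
    if bandwidth is None:
        bandwidth = (scott_bandwidth(x), scott_bandwidth(y))
    bx, by = bandwidth
    if bx <= 0 or by <= 0:
        raise ValueError("bandwidths must be positive")
    if extent is None:
        extent = (x.min() - 3 * bx, x.max() + 3 * bx,
                  y.min() - 3 * by, y.max() + 3 * by)
    xg = np.linspace(extent[0], extent[1], gridsize)
    yg = np.linspace(extent[2], extent[3], gridsize)
    # separable kernel: density = (Ky @ Kx^T summed over points) / n
    kx = np.exp(-0.5 * ((xg[None, :] - x[:, None]) / bx) ** 2) / (bx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((yg[None, :] - y[:, None]) / by) ** 2) / (by * np.sqrt(2 * np.pi))
    dens = (ky.T @ kx) / len(x)
    return xg, yg, dens


def cumulative_pdi_curve(pdis_min, top_quantile: float | None = None):
    """Empirical CDF of post-dive interval durations.

    Returns a DataFrame of (pdi_min, cdf), monotone nondecreasing and ending
    at 1. ``top_quantile=0.98`` restricts to the top 2% band, the zoom used
    to inspect extended surface intervals.
    """
    pdis = np.sort(pd.to_numeric(pd.Series(pdis_min), errors="coerce").dropna().to_numpy())
    if pdis.size == 0:
        raise ValueError("no PDIs supplied")
    cdf = np.arange(1, pdis.size + 1) / pdis.size
    out = pd.DataFrame({"pdi_min": pdis, "cdf": cdf})
    if top_quantile is not None:
        out = out[out["cdf"] >= top_quantile].reset_index(drop=True)
    return out


def trend_smooth(day_of_trip, y, span: float = 0.3, n_boot: int = 200,
                 seed: int = 0, grid=None):
    """LOESS (local linear, tricube) day-of-trip trend with a bootstrap band.

    Fits at ``grid`` (default: the sorted unique x values) and adds pointwise
    95% bands from ``n_boot`` case resamples. Returns a DataFrame with
    columns (x, fit, lo, hi).
    """
    x = np.asarray(day_of_trip, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 points")
    if span * len(x) < 4:
        raise ValueError("span too small for the data density")
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    fit = lowess(y, x, frac=span, xvals=grid)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        boot[b] = lowess(y[idx], x[idx], frac=span, xvals=grid)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame({"x": grid, "fit": fit, "lo": lo, "hi": hi})
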