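"""Prey-capture-attempt (jaw-motion) metrics.

Jaw-motion events detected by an accelerometer are a per-attempt proxy for
foraging effort. This module bins event timestamps into trip days, attaches
depths by interpolating the TDR record, and computes the share of at-sea time
spent in foraging dives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tdr import DepthRecord, DiveTable

__all__ = [
    "events_per_day",
    "event_depths",
    "percent_time_foraging",
]

#: Daily event count above which a day counts as full-effort foraging.
HIGH_EFFORT_THRESHOLD = 1500


def events_per_day(events, trip_start: float, trip_days: float | None = None,
                   threshold: int = HIGH_EFFORT_THRESHOLD) -> pd.DataFrame:
    """Daily jaw-motion counts in 24-h bins anchored at ``trip_start``.

    Day bins follow day-of-trip (not civil midnight) so indices line up with
    day-of-trip plots. Every day is returned, including zero-count days, with
    a flag for days above the full-effort ``threshold``.
    """
    events = np.asarray(events, dtype=float)
    if trip_days is None:
        if events.size == 0:
            raise ValueError("trip_days required when there are no events")
        trip_days = (events.max() - trip_start) / 86400.0
    n_days = int(np.ceil(trip_days))
    day_idx = np.floor((events - trip_start) / 86400.0).astype(int)
    if events.size and (day_idx.min() < 0 or day_idx.max() >= n_days):
        raise ValueError("events outside the trip span")
    counts = np.bincount(day_idx, minlength=n_days) if events.size else np.zeros(n_days, int)
    return pd.DataFrame({
        "trip_day": np.arange(n_days),
        "count": counts,
        "high_effort": counts > threshold,
    })


def event_depths(events, record: DepthRecord, bin_width_m: float = 10.0):
    """Depth of each event by linear interpolation of the depth record.

    Events outside the record span are flagged and excluded. Returns a dict
    with per-event depths, per-trip-day mean depths and a normalized binned
    density (integrates to 1 over the bins).
    """
    events = np.asarray(events, dtype=float)
    inside = (events >= record.times[0]) & (events <= record.times[-1])
    depths = np.interp(events[inside], record.times, record.depths)
    if depths.size:
        edges = np.arange(0.0, depths.max() + bin_width_m, bin_width_m)
        density, edges = np.histogram(depths, bins=edges, density=True)
    else:
        density, edges = np.array([]), np.array([0.0])
    day = np.floor((events[inside] - record.times[0]) / 86400.0).astype(int)
    daily_mean = pd.Series(depths).groupby(day).mean() if depths.size else pd.Series(dtype=float)
    return {
        "depths_m": depths,
        "excluded": int((~inside).sum()),
        "daily_mean_m": daily_mean,
        "density": density,
        "bin_edges_m": edges,
    }


def percent_time_foraging(events, dives: DiveTable, min_events: int = 1):
    """Percent of at-sea time spent in foraging dives.

    A dive is a foraging dive if it contains at least ``min_events`` jaw
    events. The denominator is total at-sea time — dive durations plus the
    post-dive intervals between them. Returns (trip_pct, daily DataFrame).
    """
    if len(dives) == 0:
        return 0.0, pd.DataFrame(columns=["trip_day", "pct"])
    events = np.sort(np.asarray(events, dtype=float))
    df = dives.df
    starts = df["start_time"].to_numpy(float)
    ends = df["end_time"].to_numpy(float)
    n_in_dive = (np.searchsorted(events, ends, side="right")
                 - np.searchsorted(events, starts, side="left"))
    foraging = n_in_dive >= min_events
    dur = (ends - starts)

    total_at_sea = ends[-1] - starts[0]
    trip_pct = 100.0 * dur[foraging].sum() / total_at_sea if total_at_sea > 0 else 0.0

    day = np.floor((starts - starts[0]) / 86400.0).astype(int)
    daily = pd.DataFrame({"trip_day": day, "dur": dur, "foraging": foraging})
    # per-day denominator: dive time + PDI time attributed to that day's dives
    pdi_s = df["pdi_min"].to_numpy(float) * 60.0
    daily["cycle"] = dur + np.nan_to_num(pdi_s)
    g = daily.groupby("trip_day")
    out = pd.DataFrame({
        "trip_day": sorted(daily["trip_day"].unique()),
        "pct": (g.apply(lambda s: 100.0 * s.loc[s["foraging"], "dur"].sum()
                        / s["cycle"].sum(), include_groups=False)).to_numpy(),
    })
    return float(trip_pct), out
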