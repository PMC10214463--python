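"""Seeded synthetic foraging trips with ground truth.

Generates the full data bundle the analysis consumes — depth series, location
track, jaw-motion (prey-capture-attempt) event times and paired
departure/arrival morphometry — with the statistical structure of a
post-breeding elephant seal trip: 20–40 min dive cycles to 400–600 m with a
day/night depth difference, ~2 min right-skewed post-dive intervals (PDIs),
1000–1500 prey-capture attempts per day, linear pressure-sensor drift and
Gaussian depth noise. A "sick" regime reproduces the anomalies of an at-sea
illness: extended 3–30 min PDIs across a day-indexed illness window, rare
30–200 min surface periods afterwards, suppressed foraging (<500 events/day)
and a declining dive-duration trend.

Every quantity the generator draws is recorded in a ground-truth dive table
before sensor corruption is applied, so detection and summary code can be
scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .geo import Track, solar_elevation
from .morphometrics import MorphometryRecord
from .tdr import DIVE_COLUMNS, DepthRecord, DiveTable

__all__ = [
    "SimConfig",
    "SimulatedTrip",
    "simulate_trip",
    "simulate_jaw_events",
    "simulate_morphometry_pair",
    "healthy_config",
    "sick_config",
]

#: Default trip start: 1 March, start of the post-breeding trip season.
DEFAULT_START = datetime(2017, 3, 1, tzinfo=timezone.utc).timestamp()

#: Año Nuevo colony.
COLONY_LATLON = (37.108, -122.336)


@dataclass
class SimConfig:
    """Parameters of one simulated trip.

    Durations are minutes, depths metres, rates m/s unless noted. The illness
    window is a half-open day-of-trip interval [start_day, end_day): dives
    ending on those days draw PDIs log-uniformly from ``illness_pdi_range``
    and daily jaw-event counts use ``events_per_day_sick``. After the window,
    each dive's PDI is replaced with probability ``late_extended_pdi_prob``
    by a draw from ``late_extended_pdi_range``.
    """

    seed: int
    trip_days: float = 80.0
    sample_interval: float = 8.0              # s
    start_time: float = DEFAULT_START         # epoch s, UTC
    dive_duration_mean: float = 21.0          # min
    dive_duration_sd: float = 4.0
    duration_trend_min_per_day: float = 0.0   # drift of the duration mean
    dive_depth_day_mean: float = 570.0        # m
    dive_depth_night_mean: float = 490.0
    dive_depth_sd: float = 100.0
    pdi_mean: float = 2.1                     # min, healthy regime
    pdi_sd: float = 1.0
    pdi_floor: float = 0.5                    # min, truncation floor
    descent_rate: float = 1.3                 # m/s
    ascent_rate: float = 1.2
    wiggle_rate: float = 1.0                  # wiggles per bottom-minute
    wiggle_amplitude: float = 15.0            # m
    illness_window: tuple | None = None       # (start_day, end_day)
    illness_pdi_range: tuple = (3.0, 30.0)    # min
    late_extended_pdi_prob: float = 0.0       # per-dive, after the window
    late_extended_pdi_range: tuple = (30.0, 200.0)
    events_per_day_healthy: float = 1250.0
    events_per_day_sick: float = 250.0
    sensor_offset_start: float = 0.0          # m, linear drift over the trip
    sensor_offset_end: float = 5.0
    noise_sd: float = 0.2                     # m
    colony_latlon: tuple = COLONY_LATLON
    daily_displacement_km: float = 70.0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0 or self.trip_days <= 0:
            raise ValueError("trip_days and sample_interval must be positive")
        for name in ("dive_duration_sd", "dive_depth_sd", "pdi_sd", "noise_sd",
                     "wiggle_rate", "wiggle_amplitude", "late_extended_pdi_prob",
                     "events_per_day_healthy", "events_per_day_sick"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.descent_rate <= 0 or self.ascent_rate <= 0:
            raise ValueError("descent and ascent rates must be positive")
        if self.illness_window is not None:
            lo, hi = self.illness_window
            if not (0 <= lo <= hi <= self.trip_days):
                raise ValueError("illness window must lie within [0, trip_days]")
        # a dive at the mean depth must fit transit plus some bottom time
        # inside the mean duration, else the configuration is incoherent
        transit_min = (max(self.dive_depth_day_mean, self.dive_depth_night_mean)
                       * (1 / self.descent_rate + 1 / self.ascent_rate) / 60.0)
        if self.dive_duration_mean <= transit_min:
            raise ValueError(
                f"mean dive duration {self.dive_duration_mean} min cannot reach "
                f"the mean depth given the rates (transit alone is "
                f"{transit_min:.1f} min)"
            )

    def in_illness_window(self, day: float) -> bool:
        if self.illness_window is None:
            return False
        lo, hi = self.illness_window
        return lo <= day < hi


@dataclass
class SimulatedTrip:
    """One simulated trip: corrupted sensor record plus ground truth."""

    config: SimConfig
    depth_record: DepthRecord          # with sensor offset + noise applied
    clean_depths: np.ndarray           # same grid, before corruption
    truth_dives: DiveTable
    track: Track
    jaw_events: np.ndarray             # epoch s
    morphometry_pair: tuple            # (departure, arrival) MorphometryRecord


def healthy_config(seed: int, trip_days: float = 80.0, **kw) -> SimConfig:
    """A typical healthy post-breeding trip."""
    return SimConfig(seed=seed, trip_days=trip_days, **kw)


def sick_config(seed: int, trip_days: float = 91.0, **kw) -> SimConfig:
    """The illness regime: extended PDIs on days 8–20, rare very long surface
    periods afterwards, suppressed foraging and declining dive durations."""
    defaults = dict(
        illness_window=(8.0, 20.0),
        late_extended_pdi_prob=0.01,
        duration_trend_min_per_day=-0.07,
        dive_duration_mean=19.0,
        dive_depth_day_mean=450.0,
        dive_depth_night_mean=410.0,
    )
    defaults.update(kw)
    return SimConfig(seed=seed, trip_days=trip_days, **defaults)


def _lognormal_params(mean: float, sd: float):
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _draw_pdi(rng: np.random.Generator, config: SimConfig, day: float) -> float:
    """PDI (min) under the regime active on trip day ``day``."""
    if config.in_illness_window(day):
        lo, hi = config.illness_pdi_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if (config.illness_window is not None and day >= config.illness_window[1]
            and rng.random() < config.late_extended_pdi_prob):
        lo, hi = config.late_extended_pdi_range
        return float(rng.uniform(lo, hi))
    mu, sigma = _lognormal_params(config.pdi_mean, config.pdi_sd)
    for _ in range(100):
        x = float(rng.lognormal(mu, sigma))
        if x >= config.pdi_floor:
            return x
    return config.pdi_floor


def simulate_trip(config: SimConfig) -> SimulatedTrip:
    """Generate a complete seeded trip (deterministic for a fixed seed).

    The depth series is a concatenation of dive cycles — constant-rate
    descent, bottom phase with whole-cycle sinusoidal wiggles, constant-rate
    ascent — separated by PDIs drawn from the regime active on the dive's
    trip day. Day dives use the (deeper) daytime depth mean, judged by solar
    elevation at the colony longitude. The linear sensor offset and Gaussian
    noise are applied last; the truth table records the uncorrupted
    start/end/depth/duration/PDI of every dive.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sample_interval
    span_s = config.trip_days * 86400.0
    n = int(np.floor(span_s / dt)) + 1
    times = config.start_time + dt * np.arange(n)
    clean = np.zeros(n)

    rows = []
    t = _draw_pdi(rng, config, 0.0) * 60.0       # start at the surface
    while True:
        is_day = solar_elevation(config.start_time + t, *config.colony_latlon) > 0
        depth_mean = (config.dive_depth_day_mean if is_day
                      else config.dive_depth_night_mean)
        depth = float(np.clip(rng.normal(depth_mean, config.dive_depth_sd),
                              100.0, 1500.0))
        desc_t = depth / config.descent_rate
        asc_t = depth / config.ascent_rate
        dur_mean = (config.dive_duration_mean
                    + config.duration_trend_min_per_day * (t / 86400.0))
        dur_s = rng.normal(dur_mean, config.dive_duration_sd) * 60.0
        dur_s = max(dur_s, desc_t + asc_t + 4 * dt)   # always some bottom time
        if t + dur_s > span_s - 60.0:
            break
        bottom_t = dur_s - desc_t - asc_t
        n_wig = int(np.floor(config.wiggle_rate * bottom_t / 60.0))
        amp = min(0.5 * config.wiggle_amplitude, 0.5 * depth)

        i0 = int(np.ceil(t / dt))
        i1 = int(np.floor((t + dur_s) / dt))
        tau = dt * np.arange(i0, i1 + 1) - t
        seg = np.zeros_like(tau)
        desc = tau < desc_t
        seg[desc] = depth / desc_t * tau[desc]
        asc = tau > dur_s - asc_t
        seg[asc] = depth / asc_t * (dur_s - tau[asc])
        bot = ~desc & ~asc
        if bot.any() and bottom_t > 0 and n_wig > 0:
            phase = (tau[bot] - desc_t) / bottom_t
            seg[bot] = depth - amp * (1 - np.cos(2 * np.pi * n_wig * phase))
        elif bot.any():
            seg[bot] = depth
        clean[i0:i1 + 1] = seg

        end_day = (t + dur_s) / 86400.0
        pdi = _draw_pdi(rng, config, end_day)
        rows.append({
            "start_idx": i0, "end_idx": i1,
            "start_time": config.start_time + t,
            "end_time": config.start_time + t + dur_s,
            "max_depth_m": depth, "duration_min": dur_s / 60.0,
            "bottom_time_min": bottom_t / 60.0,
            "descent_rate_ms": config.descent_rate,
            "ascent_rate_ms": config.ascent_rate,
            "n_wiggles": n_wig, "pdi_min": pdi,
            "is_day": bool(is_day), "lat": np.nan, "lon": np.nan,
            "located": False, "degenerate": False,
        })
        t = t + dur_s + pdi * 60.0

    if rows:
        rows[-1]["pdi_min"] = np.nan          # no successor dive
    truth = DiveTable(pd.DataFrame(rows))

    offset = np.linspace(config.sensor_offset_start, config.sensor_offset_end, n)
    observed = clean + offset + rng.normal(0.0, config.noise_sd, n)
    record = DepthRecord(times, observed, dt)

    track = _simulate_track(rng, config)
    events = simulate_jaw_events(config, truth, rng=rng)
    morpho = simulate_morphometry_pair(
        rng, sick=config.illness_window is not None)
    return SimulatedTrip(config, record, clean, truth, track, events, morpho)


def _simulate_track(rng: np.random.Generator, config: SimConfig) -> Track:
    """Hourly out-and-back correlated random walk from the colony.

    Outbound headings follow a persistent random walk at the configured daily
    displacement; the return leg retraces the outbound path, so the trip ends
    at the colony. Downstream analysis uses only distances and interpolation,
    for which this is adequate.
    """
    n_hours = int(np.floor(config.trip_days * 24))
    n_out = n_hours // 2
    step_km = config.daily_displacement_km / 24.0
    heading = rng.uniform(0, 2 * np.pi)
    lat = [config.colony_latlon[0]]
    lon = [config.colony_latlon[1]]
    for _ in range(n_out):
        heading += rng.normal(0.0, 0.15)
        dlat = step_km * np.cos(heading) / 111.32
        dlon = step_km * np.sin(heading) / (111.32 * np.cos(np.radians(lat[-1])))
        lat.append(np.clip(lat[-1] + dlat, -89.0, 89.0))
        lon.append(lon[-1] + dlon)
    lat_back = lat[-2::-1]
    lon_back = lon[-2::-1]
    lat = np.array(lat + lat_back, dtype=float)
    lon = np.array(lon + lon_back, dtype=float)
    times = config.start_time + 3600.0 * np.arange(len(lat))
    return Track(times, lat, lon)


def simulate_jaw_events(config: SimConfig, truth_dives: DiveTable,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Prey-capture-attempt timestamps placed uniformly in dive bottom phases.

    Each trip day draws a Poisson count at the regime rate (healthy, or sick
    inside the illness window) and spreads the events uniformly over the
    concatenated bottom-phase time of dives starting that day, so every event
    falls inside a dive and expected daily counts equal the regime rate.
    """
    if len(truth_dives) == 0:
        raise ValueError("truth dive table is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    df = truth_dives.df
    start = df["start_time"].to_numpy(float)
    day_idx = np.floor((start - config.start_time) / 86400.0).astype(int)
    bot_start = start + df["max_depth_m"].to_numpy(float) / df["descent_rate_ms"].to_numpy(float)
    bot_len = df["bottom_time_min"].to_numpy(float) * 60.0

    events = []
    for day in range(int(np.ceil(config.trip_days))):
        rate = (config.events_per_day_sick if config.in_illness_window(day)
                else config.events_per_day_healthy)
        sel = np.where(day_idx == day)[0]
        if sel.size == 0 or rate == 0:
            continue
        total_bottom = bot_len[sel].sum()
        if total_bottom <= 0:
            continue
        n_ev = rng.poisson(rate)
        if n_ev == 0:
            continue
        u = rng.uniform(0.0, total_bottom, n_ev)
        edges = np.r_[0.0, np.cumsum(bot_len[sel])]
        which = np.searchsorted(edges, u, side="right") - 1
        events.append(bot_start[sel[which]] + (u - edges[which]))
    if not events:
        return np.array([], dtype=float)
    return np.sort(np.concatenate(events))


def simulate_morphometry_pair(rng: np.random.Generator, sick: bool = False):
    """Paired departure/arrival morphometry records.

    Healthy trips gain ~87 kg and blubber; the sick regime loses ~49 kg with
    blubber thinning from ~2.6 to ~1.7 cm, the pattern of a failed trip.
    Girths scale with the cube root of the mass ratio.
    """
    girth_shape = np.array([1.05, 1.55, 1.75, 1.65, 1.35, 0.95])  # x length/2.53
    if sick:
        dep_mass, arr_mass = 294.0, 245.0
        dep_blub, arr_blub = 25.5, 17.2
        length = 253.0
    else:
        dep_mass = float(rng.normal(290.0, 15.0))
        arr_mass = dep_mass + float(rng.normal(87.0, 15.0))
        dep_blub, arr_blub = 33.5, 37.9
        length = float(rng.normal(261.0, 9.0))
    girths_dep = girth_shape * length / 2.53
    girths_arr = girths_dep * (arr_mass / dep_mass) ** (1 / 3)

    def rec(mass, girths, blub, stage):
        jitter = rng.normal(0, 1.0, 6)
        return MorphometryRecord(
            mass_kg=mass, standard_length_cm=length, girths_cm=girths,
            blubber_dorsal_mm=np.clip(blub + jitter, 1.0, None),
            blubber_lateral_mm=np.clip(blub + rng.normal(0, 1.0, 6), 1.0, None),
            fasting_days=2.0, stage=stage,
        )

    return rec(dep_mass, girths_dep, dep_blub, "departure"), \
        rec(arr_mass, girths_arr, arr_blub, "arrival")
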