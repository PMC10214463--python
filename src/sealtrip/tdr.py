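"""Time-depth-recorder processing: zero-offset correction, dive detection and
per-dive statistics.

A TDR archives depth (m, positive down) at a fixed sampling interval. Pressure
sensors drift, so the record is first zero-offset corrected (ZOC) so that
surface readings sit at 0 m. Dives are then maximal submergences exceeding a
depth and duration threshold, and each dive gets the standard statistics used
in pinniped diving studies: maximum depth, duration, bottom time, descent and
ascent rates, bottom-phase wiggles, and the post-dive surface interval (PDI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "DepthRecord",
    "DiveTable",
    "zero_offset_correct",
    "subsample",
    "detect_dives",
    "dive_stats",
    "extended_surface_intervals",
    "split_on_gaps",
]

#: Column order of a dive table.
DIVE_COLUMNS = [
    "start_idx", "end_idx", "start_time", "end_time",
    "max_depth_m", "duration_min", "bottom_time_min",
    "descent_rate_ms", "ascent_rate_ms", "n_wiggles",
    "pdi_min", "is_day", "lat", "lon", "located", "degenerate",
]


@dataclass
class DepthRecord:
    """Regularly sampled depth series.

    Parameters
    ----------
    times : ndarray
        Seconds since the Unix epoch (UTC), strictly increasing and regular.
    depths : ndarray
        Depth in metres, positive down. Must be finite.
    sample_interval : float
        Sampling interval in seconds.
    """

    times: np.ndarray
    depths: np.ndarray
    sample_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape or self.times.ndim != 1:
            raise ValueError("times and depths must be 1-D arrays of equal length")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not np.all(np.isfinite(self.depths)):
            raise ValueError("depths must be finite")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            # regular within 1 ms; larger steps are gaps the caller must split on
            if np.any(np.abs(dt - self.sample_interval) > 1e-3):
                raise ValueError(
                    "sampling is irregular; use split_on_gaps() on the raw "
                    "arrays before constructing a DepthRecord"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def split_on_gaps(times, depths, sample_interval, tol=1e-3):
    """Split raw (times, depths) arrays into gap-free DepthRecords.

    Samples separated by more than ``sample_interval + tol`` seconds start a new
    segment. PDIs across a gap are undefined, so each segment is analysed
    independently downstream.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if len(times) == 0:
        return []
    breaks = np.where(np.abs(np.diff(times) - sample_interval) > tol)[0] + 1
    segments = []
    for t, d in zip(np.split(times, breaks), np.split(depths, breaks)):
        if len(t) >= 2:
            segments.append(DepthRecord(t, d, sample_interval))
    return segments


@dataclass
class DiveTable:
    """Ordered, non-overlapping table of detected (or simulated) dives.

    Thin wrapper around a pandas DataFrame with the columns in
    :data:`DIVE_COLUMNS`; one row per dive.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DIVE_COLUMNS))

    def __post_init__(self) -> None:
        for col in DIVE_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[DIVE_COLUMNS].reset_index(drop=True)
        if len(self.df) > 1:
            starts = self.df["start_time"].to_numpy(float)
            ends = self.df["end_time"].to_numpy(float)
            if np.any(np.diff(starts) <= 0):
                raise ValueError("dives must be time-ordered")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("dives must not overlap")

    def __len__(self) -> int:
        return len(self.df)


def zero_offset_correct(record: DepthRecord, window_min: float = 60.0,
                        percentile: float = 2.0):
    """Remove pressure-sensor surface drift from a depth record.

    The surface baseline is the rolling lower ``percentile`` of depth in
    consecutive windows of ``window_min`` minutes, linearly interpolated
    between window centres, then subtracted. Residual negative depths are
    clipped to 0. The window must contain surface time in every window — under
    a 20–40 min dive-cycle regime a 60 min window always does.

    Returns
    -------
    (DepthRecord, ndarray)
        The corrected record and the estimated baseline at every sample.
    """
    window_s = window_min * 60.0
    if window_s < 10 * record.sample_interval:
        raise ValueError("window must cover at least 10 samples")
    n_per_win = int(round(window_s / record.sample_interval))
    n = len(record)
    if n < n_per_win:
        raise ValueError("record too short for the requested ZOC window")

    centres, levels = [], []
    for lo in range(0, n, n_per_win):
        hi = min(lo + n_per_win, n)
        centres.append(0.5 * (record.times[lo] + record.times[hi - 1]))
        levels.append(np.percentile(record.depths[lo:hi], percentile))
    baseline = np.interp(record.times, centres, levels)
    corrected = np.clip(record.depths - baseline, 0.0, None)
    return replace(record, depths=corrected), baseline


def subsample(record: DepthRecord, target_interval: float) -> DepthRecord:
    """Decimate to ``target_interval`` seconds by keeping every k-th sample.

    ``target_interval`` must be an integer multiple of the native interval;
    the first sample is always retained.
    """
    ratio = target_interval / record.sample_interval
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target interval {target_interval}s is not an integer multiple "
            f"of the native {record.sample_interval}s"
        )
    if k == 1:
        return record
    return DepthRecord(record.times[::k], record.depths[::k], target_interval)


def detect_dives(record: DepthRecord, min_depth: float = 15.0,
                 min_duration: float = 32.0, surface_threshold: float = 2.0,
                 bottom_fraction: float = 0.8, wiggle_min: float = 5.0) -> DiveTable:
    """Detect dives in a zero-offset-corrected record.

    A dive is a maximal contiguous run of samples with depth >
    ``surface_threshold`` whose maximum depth reaches ``min_depth`` m and
    whose duration reaches ``min_duration`` s. Start/end indices are the
    surface samples bracketing the submergence. The PDI of a dive is the gap
    from its end to the next dive's start (NaN for the last dive). Statistics
    are filled by :func:`dive_stats`.
    """
    depths = record.depths
    wet = depths > surface_threshold
    if not wet.any():
        return DiveTable()
    # run boundaries of the wet mask
    edges = np.diff(wet.astype(np.int8))
    run_starts = np.where(edges == 1)[0] + 1
    run_ends = np.where(edges == -1)[0]          # last wet index of each run
    if wet[0]:
        run_starts = np.r_[0, run_starts]
    if wet[-1]:
        run_ends = np.r_[run_ends, len(wet) - 1]

    dives = []
    for rs, re in zip(run_starts, run_ends):
        start = max(rs - 1, 0)                   # bracketing surface samples
        end = min(re + 1, len(depths) - 1)
        duration_s = record.times[end] - record.times[start]
        if depths[rs:re + 1].max() < min_depth or duration_s < min_duration:
            continue
        dives.append((start, end))
    if not dives:
        return DiveTable()

    rows = []
    for i, (start, end) in enumerate(dives):
        d = dive_stats(record, start, end, bottom_fraction=bottom_fraction,
                       wiggle_min=wiggle_min)
        if i + 1 < len(dives):
            d["pdi_min"] = (record.times[dives[i + 1][0]] - record.times[end]) / 60.0
        else:
            d["pdi_min"] = np.nan
        rows.append(d)
    return DiveTable(pd.DataFrame(rows))


def dive_stats(record: DepthRecord, start_idx: int, end_idx: int,
               bottom_fraction: float = 0.8, wiggle_min: float = 5.0) -> dict:
    """Compute the standard per-dive statistics for one dive.

    The bottom phase is the span of samples with depth >= ``bottom_fraction`` x
    max depth. Descent rate is (first bottom-phase depth - start depth) over
    the elapsed time; ascent rate symmetric from the last bottom-phase sample.
    Wiggles are local depth maxima inside the bottom phase with prominence >=
    ``wiggle_min`` m. A degenerate (<3 sample) dive gets zeroed stats and a
    ``degenerate`` flag.
    """
    t = record.times[start_idx:end_idx + 1]
    z = record.depths[start_idx:end_idx + 1]
    row = {
        "start_idx": start_idx, "end_idx": end_idx,
        "start_time": t[0], "end_time": t[-1],
        "max_depth_m": float(z.max()),
        "duration_min": (t[-1] - t[0]) / 60.0,
        "bottom_time_min": 0.0, "descent_rate_ms": 0.0, "ascent_rate_ms": 0.0,
        "n_wiggles": 0, "pdi_min": np.nan,
        "is_day": np.nan, "lat": np.nan, "lon": np.nan,
        "located": False, "degenerate": False,
    }
    if len(z) < 3 or row["duration_min"] <= 0:
        warnings.warn("degenerate dive: statistics set to 0", stacklevel=2)
        row["degenerate"] = True
        return row

    cutoff = bottom_fraction * z.max()
    bottom = np.where(z >= cutoff)[0]
    b0, b1 = bottom[0], bottom[-1]
    row["bottom_time_min"] = (t[b1] - t[b0]) / 60.0
    if b0 > 0:
        row["descent_rate_ms"] = float((z[b0] - z[0]) / (t[b0] - t[0]))
    if b1 < len(z) - 1:
        row["ascent_rate_ms"] = float((z[b1] - z[-1]) / (t[-1] - t[b1]))
    if b1 > b0:
        peaks, _ = find_peaks(z[b0:b1 + 1], prominence=wiggle_min)
        row["n_wiggles"] = int(len(peaks))
    return row


def extended_surface_intervals(dives: DiveTable, threshold_min: float = 4.0):
    """Post-dive intervals strictly longer than ``threshold_min`` minutes.

    Returns (count, DataFrame) where the frame carries the PDI duration, the
    time the interval started (dive end), and the dive's day/night flag.
    """
    if len(dives) == 0:
        raise ValueError("dive table is empty")
    df = dives.df
    sel = df["pdi_min"] > threshold_min
    out = df.loc[sel, ["end_time", "pdi_min", "is_day"]].reset_index(drop=True)
    return int(sel.sum()), out
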