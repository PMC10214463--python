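"""CSV readers and writers for the trip data bundle.

All timestamps on disk are ISO-8601 UTC (e.g. ``2017-03-01T00:00:08Z``);
in memory they are float seconds since the Unix epoch. Schemas:

- depth:       ``time,depth_m``
- track:       ``time,lat,lon``
- events:      ``time``
- dive table:  the columns of :data:`sealtrip.tdr.DIVE_COLUMNS` with the two
               time columns serialized as ISO-8601
- morphometry: one row per sedation — mass, length, fasting days, stage,
               six girths and six dorsal + six lateral blubber thicknesses
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import Track
from .morphometrics import MorphometryRecord
from .tdr import DIVE_COLUMNS, DepthRecord, DiveTable, split_on_gaps

__all__ = [
    "read_depth_csv", "write_depth_csv",
    "read_track_csv", "write_track_csv",
    "read_events_csv", "write_events_csv",
    "read_dive_csv", "write_dive_csv",
    "read_morphometry_csv", "write_morphometry_csv",
    "write_trip",
]


def _to_iso(seconds) -> pd.Series:
    return pd.to_datetime(np.asarray(seconds, dtype=float), unit="s", utc=True) \
        .strftime("%Y-%m-%dT%H:%M:%SZ")


def _from_iso(col) -> np.ndarray:
    return pd.to_datetime(col, utc=True).astype("int64").to_numpy() / 1e9


def write_depth_csv(record: DepthRecord, path) -> None:
    pd.DataFrame({"time": _to_iso(record.times),
                  "depth_m": record.depths}).to_csv(path, index=False)


def read_depth_csv(path, sample_interval: float | None = None):
    """Read a depth CSV into gap-free DepthRecord segments.

    The sampling interval is inferred from the median time step unless given.
    Returns a list of segments (one when the record has no gaps).
    """
    df = pd.read_csv(path)
    times = _from_iso(df["time"])
    if sample_interval is None:
        sample_interval = float(np.median(np.diff(times)))
    return split_on_gaps(times, df["depth_m"].to_numpy(float), sample_interval)


def write_track_csv(track: Track, path) -> None:
    pd.DataFrame({"time": _to_iso(track.times), "lat": track.lat,
                  "lon": track.lon}).to_csv(path, index=False)


def read_track_csv(path) -> Track:
    df = pd.read_csv(path)
    return Track(_from_iso(df["time"]), df["lat"].to_numpy(float),
                 df["lon"].to_numpy(float))


def write_events_csv(events, path) -> None:
    pd.DataFrame({"time": _to_iso(events)}).to_csv(path, index=False)


def read_events_csv(path) -> np.ndarray:
    return _from_iso(pd.read_csv(path)["time"])


def write_dive_csv(dives: DiveTable, path) -> None:
    df = dives.df.copy()
    for col in ("start_time", "end_time"):
        df[col] = _to_iso(df[col])
    df.to_csv(path, index=False)


def read_dive_csv(path) -> DiveTable:
    df = pd.read_csv(path)
    for col in ("start_time", "end_time"):
        df[col] = _from_iso(df[col])
    return DiveTable(df[DIVE_COLUMNS])


def write_morphometry_csv(records, path) -> None:
    rows = []
    for m in records:
        row = {"stage": m.stage, "mass_kg": m.mass_kg,
               "standard_length_cm": m.standard_length_cm,
               "fasting_days": m.fasting_days}
        for i in range(6):
            row[f"girth{i + 1}_cm"] = m.girths_cm[i]
            row[f"blubber_dorsal{i + 1}_mm"] = m.blubber_dorsal_mm[i]
            row[f"blubber_lateral{i + 1}_mm"] = m.blubber_lateral_mm[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_morphometry_csv(path):
    df = pd.read_csv(path)
    records = []
    for _, r in df.iterrows():
        records.append(MorphometryRecord(
            mass_kg=r["mass_kg"], standard_length_cm=r["standard_length_cm"],
            girths_cm=[r[f"girth{i + 1}_cm"] for i in range(6)],
            blubber_dorsal_mm=[r[f"blubber_dorsal{i + 1}_mm"] for i in range(6)],
            blubber_lateral_mm=[r[f"blubber_lateral{i + 1}_mm"] for i in range(6)],
            fasting_days=r["fasting_days"], stage=r["stage"],
        ))
    return records


def write_trip(trip, outdir) -> None:
    """Write a SimulatedTrip's full bundle (depth, truth dives, track, events,
    morphometry) into ``outdir``."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_depth_csv(trip.depth_record, out / "depth.csv")
    write_dive_csv(trip.truth_dives, out / "truth_dives.csv")
    write_track_csv(trip.track, out / "track.csv")
    write_events_csv(trip.jaw_events, out / "events.csv")
    write_morphometry_csv(trip.morphometry_pair, out / "morphometry.csv")
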