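"""Interpolate a track, compute distances, and classify dives day/night.

Distances use the haversine great circle; day/night uses the geometric solar
elevation (NOAA series) at each dive's interpolated position.
"""

from sealtrip import synthetic
from sealtrip.geo import classify_day_night, interpolate_track, trip_distances

trip = synthetic.simulate_trip(synthetic.healthy_config(seed=11, trip_days=30.0))
track = interpolate_track(trip.track, interval_hours=1.0)
total_km, max_km = trip_distances(track, trip.config.colony_latlon)
print(f"total distance {total_km:.0f} km, max from colony {max_km:.0f} km")

classify_day_night(trip.truth_dives, track)
df = trip.truth_dives.df
day = df[df["is_day"] == True]   # noqa: E712
night = df[df["is_day"] == False]  # noqa: E712
print(f"{len(day)} day dives (mean depth {day['max_depth_m'].mean():.0f} m), "
      f"{len(night)} night dives (mean depth {night['max_depth_m'].mean():.0f} m)")
print("day dives run deeper: prey in the deep scattering layer migrate "
      "down at dawn")
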