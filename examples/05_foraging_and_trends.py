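"""Foraging metrics and trip-level summaries for a sick vs healthy pair.

Daily prey-capture-attempt counts, percent time foraging, the LOESS
dive-duration trend, and the trip-report table.
"""

import numpy as np

from sealtrip import synthetic
from sealtrip.foraging import events_per_day, percent_time_foraging
from sealtrip.summaries import trend_smooth, trip_summary

sick = synthetic.simulate_trip(synthetic.sick_config(seed=2, trip_days=25.0))
healthy = synthetic.simulate_trip(synthetic.healthy_config(seed=2, trip_days=25.0))

daily = events_per_day(sick.jaw_events, sick.config.start_time, 25.0)
window = daily["trip_day"].between(8, 19)
print(f"sick trip: {daily.loc[window, 'count'].mean():.0f} attempts/day in the "
      f"illness window vs {daily.loc[~window, 'count'].mean():.0f} outside")

for name, trip in (("sick", sick), ("healthy", healthy)):
    pct, _ = percent_time_foraging(trip.jaw_events, trip.truth_dives)
    print(f"{name}: {pct:.0f}% of at-sea time in foraging dives")

df = sick.truth_dives.df
day = (df["start_time"].to_numpy() - sick.config.start_time) / 86400.0
trend = trend_smooth(day, df["duration_min"].to_numpy(), n_boot=50, seed=0)
print(f"fitted dive duration declines {trend['fit'].iloc[0]:.1f} -> "
      f"{trend['fit'].iloc[-1]:.1f} min across the trip")

s = trip_summary(sick.truth_dives, sick.track, sick.morphometry_pair,
                 sick.jaw_events, colony_latlon=sick.config.colony_latlon)
print(f"\ntrip report: {s.n_dives} dives over {s.trip_days:.0f} days, "
      f"{s.n_pdi_gt_4min} PDIs > 4 min,")
print(f"  {s.total_distance_km:.0f} km travelled, mass change "
      f"{s.mass_gain_kg:+.1f} kg, energy change {s.energy_gain_MJ:+.0f} MJ")
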