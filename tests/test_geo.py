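"""Track geometry and solar position against closed forms and an
independent Meeus ephemeris oracle."""

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from _oracles import meeus_solar_elevation
from sealtrip.geo import (Track, classify_day_night, great_circle_km,
                          interpolate_track, solar_elevation, trip_distances)
from sealtrip.tdr import DiveTable
import pandas as pd


def utc(*args) -> float:
    return datetime(*args, tzinfo=timezone.utc).timestamp()


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km(36.0, -122.0, 36.0, -122.0) == 0.0

    def test_one_degree_equator(self):
        # 2 pi R / 360 with R = 6371 km
        assert great_circle_km(0, 0, 0, 1) == pytest.approx(111.195, abs=0.01)

    def test_quarter_meridian(self):
        assert great_circle_km(0, 0, 90, 0) == pytest.approx(np.pi * 6371 / 2,
                                                             abs=0.1)

    @given(hst.floats(-80, 80), hst.floats(-170, 170),
           hst.floats(-80, 80), hst.floats(-170, 170))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_law_of_cosines(self, lat1, lon1, lat2, lon2):
        d = great_circle_km(lat1, lon1, lat2, lon2)
        p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
        cos_c = (np.sin(p1) * np.sin(p2)
                 + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1))
        oracle = 6371.0 * np.arccos(np.clip(cos_c, -1, 1))
        if oracle > 1.0:
            assert d == pytest.approx(oracle, rel=1e-6)


class TestInterpolateTrack:
    def test_midpoint_is_average(self):
        tr = Track([0.0, 7200.0], [10.0, 12.0], [-120.0, -118.0])
        out = interpolate_track(tr, 1.0)
        assert out.lat[1] == pytest.approx(11.0)
        assert out.lon[1] == pytest.approx(-119.0)
        assert (out.times[0], out.times[-1]) == (0.0, 7200.0)

    def test_hourly_track_unchanged(self):
        tr = Track(3600.0 * np.arange(5), np.linspace(0, 1, 5),
                   np.linspace(-2, 2, 5))
        out = interpolate_track(tr, 1.0)
        np.testing.assert_allclose(out.lat, tr.lat)

    def test_stays_in_bounding_box(self, rng):
        tr = Track(np.sort(rng.uniform(0, 1e5, 10)),
                   rng.uniform(30, 40, 10), rng.uniform(-130, -120, 10))
        out = interpolate_track(tr, 0.5)
        assert out.lat.min() >= tr.lat.min() and out.lat.max() <= tr.lat.max()
        assert out.lon.min() >= tr.lon.min() and out.lon.max() <= tr.lon.max()

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            interpolate_track(Track([0.0, 0.0, 10.0], [0, 1, 2], [0, 1, 2]), 1.0)


class TestTripDistances:
    def test_stationary_track(self):
        tr = Track([0.0, 3600.0], [35.0, 35.0], [-125.0, -125.0])
        total, mx = trip_distances(tr, (36.0, -125.0))
        assert total == 0.0
        assert mx == pytest.approx(great_circle_km(35, -125, 36, -125))

    def test_out_and_back(self):
        lats = np.r_[np.linspace(37, 40, 30), np.linspace(40, 37, 30)[1:]]
        tr = Track(3600.0 * np.arange(len(lats)), lats,
                   np.full(len(lats), -125.0))
        total, mx = trip_distances(tr, (37.0, -125.0))
        assert total == pytest.approx(2 * mx, rel=1e-9)

    def test_total_at_least_max(self, sick_trip):
        total, mx = trip_distances(sick_trip.track,
                                   sick_trip.config.colony_latlon)
        assert total >= mx


class TestSolarElevation:
    def test_equator_equinox_noon_overhead(self):
        """At local solar noon (the transit, which the equation of time
        shifts off 12:00 UTC) on the equinox the Sun is overhead."""
        t = utc(2017, 3, 20, 11, 0) + 60.0 * np.arange(120)
        elev = solar_elevation(t, 0.0, 0.0)
        assert elev.max() == pytest.approx(90.0, abs=1.0)

    def test_polar_night_at_solstice(self):
        assert solar_elevation(utc(2017, 12, 21, 12, 0), 80.0, 0.0) < 0.0

    def test_continuity_in_time(self):
        t0 = utc(2017, 6, 1, 0, 0)
        t = t0 + 60.0 * np.arange(24 * 60)
        elev = solar_elevation(t, 37.1, -122.3)
        assert np.abs(np.diff(elev)).max() <= 0.5  # deg per minute

    def test_against_meeus_oracle_grid(self, rng):
        """+/-0.5 deg agreement with an independent ephemeris over a random
        space-time grid spanning several years and all latitudes."""
        times = rng.uniform(utc(2015, 1, 1), utc(2021, 1, 1), 250)
        lats = rng.uniform(-85, 85, 250)
        lons = rng.uniform(-180, 180, 250)
        for t, la, lo in zip(times, lats, lons):
            assert solar_elevation(t, la, lo) == pytest.approx(
                meeus_solar_elevation(t, la, lo), abs=0.5)


class TestClassifyDayNight:
    @staticmethod
    def _dives_at(times):
        rows = [{"start_idx": 0, "end_idx": 1, "start_time": t,
                 "end_time": t + 600.0, "max_depth_m": 500.0,
                 "duration_min": 10.0} for t in times]
        return DiveTable(pd.DataFrame(rows))

    @staticmethod
    def _track_around(times, lat, lon):
        t = np.array([min(times) - 3600, max(times) + 3600])
        return Track(t, [lat, lat], [lon, lon])

    def test_local_midnight_is_night(self):
        t = utc(2017, 6, 1, 8, 0)  # midnight local at lon -120
        dives = self._dives_at([t])
        classify_day_night(dives, self._track_around([t], 40.0, -120.0))
        assert dives.df["is_day"].iloc[0] == False  # noqa: E712

    def test_equator_noon_is_day(self):
        t = utc(2017, 3, 20, 12, 0)
        dives = self._dives_at([t])
        classify_day_night(dives, self._track_around([t], 0.0, 0.0))
        assert dives.df["is_day"].iloc[0] == True  # noqa: E712

    def test_dive_outside_track_flagged(self):
        t = utc(2017, 5, 1, 0, 0)
        dives = self._dives_at([t, t + 86400 * 30])
        classify_day_night(dives, self._track_around([t], 10.0, 10.0))
        assert bool(dives.df["located"].iloc[0])
        assert not bool(dives.df["located"].iloc[1])
        assert pd.isna(dives.df["is_day"].iloc[1])

    def test_equatorial_trip_half_day_half_night(self):
        """Dives spread over weeks at the equator split ~50/50 day/night."""
        from sealtrip import synthetic
        cfg = synthetic.healthy_config(seed=31, trip_days=20.0,
                                       colony_latlon=(0.0, -140.0))
        trip = synthetic.simulate_trip(cfg)
        classify_day_night(trip.truth_dives, trip.track)
        frac = trip.truth_dives.df["is_day"].mean()
        assert frac == pytest.approx(0.5, abs=0.02)
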