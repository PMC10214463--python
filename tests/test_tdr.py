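"""Dive processing: ZOC, subsampling, detection vs an explicit-scan oracle,
and closed-form per-dive statistics on constructed profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from _oracles import match_dives, scan_detect_dives
from sealtrip.tdr import (DepthRecord, DiveTable, detect_dives, dive_stats,
                          extended_surface_intervals, split_on_gaps,
                          subsample, zero_offset_correct)


def make_record(depths, dt=8.0, t0=0.0):
    depths = np.asarray(depths, dtype=float)
    return DepthRecord(t0 + dt * np.arange(len(depths)), depths, dt)


def square_dive_record(n_dives=5, depth=400.0, dive_samples=150,
                       surface_samples=20, dt=8.0, ramp=10):
    """Trapezoidal dives separated by flat surface, all sample-aligned."""
    out = [np.zeros(surface_samples)]
    for _ in range(n_dives):
        down = np.linspace(0, depth, ramp, endpoint=False)
        bottom = np.full(dive_samples - 2 * ramp, depth)
        up = np.linspace(depth, 0, ramp, endpoint=False)
        out += [down, bottom, up, np.zeros(surface_samples)]
    return make_record(np.concatenate(out), dt=dt)


class TestZeroOffsetCorrect:
    def test_constant_offset_removed(self, short_healthy_trip):
        clean = short_healthy_trip.clean_depths
        rec = make_record(clean + 3.0)
        corrected, baseline = zero_offset_correct(rec)
        np.testing.assert_allclose(corrected.depths, clean, atol=0.1)
        np.testing.assert_allclose(baseline, 3.0, atol=0.1)

    def test_linear_drift_removed(self, short_healthy_trip):
        clean = short_healthy_trip.clean_depths
        drift = np.linspace(0, 5.0, len(clean))
        corrected, _ = zero_offset_correct(make_record(clean + drift))
        surface = clean == 0.0
        assert np.abs(corrected.depths[surface]).max() <= 0.5

    def test_already_zeroed_is_identity(self, short_healthy_trip):
        clean = short_healthy_trip.clean_depths
        corrected, _ = zero_offset_correct(make_record(clean))
        np.testing.assert_allclose(corrected.depths, clean, atol=1e-9)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            zero_offset_correct(make_record(np.zeros(100)), window_min=60.0)


class TestSubsample:
    def test_every_kth_sample_kept(self):
        rec = make_record(np.arange(64.0), dt=1.0)
        out = subsample(rec, 8.0)
        np.testing.assert_array_equal(out.depths, np.arange(0.0, 64.0, 8.0))
        assert out.sample_interval == 8.0

    def test_native_interval_identity(self):
        rec = make_record(np.arange(10.0))
        assert subsample(rec, 8.0) is rec

    def test_sample_count(self):
        rec = make_record(np.zeros(100), dt=2.0)
        assert len(subsample(rec, 8.0)) == 25

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            subsample(make_record(np.zeros(10)), 12.0)


class TestDetectDives:
    def test_flat_record_empty(self):
        assert len(detect_dives(make_record(np.zeros(500)))) == 0

    def test_shallow_excursion_excluded(self):
        rec = square_dive_record(n_dives=1, depth=10.0)
        assert len(detect_dives(rec, min_depth=15.0)) == 0

    def test_injected_dives_recovered_exactly(self):
        rec = square_dive_record(n_dives=10)
        dives = detect_dives(rec)
        assert len(dives) == 10
        np.testing.assert_allclose(dives.df["max_depth_m"], 400.0)

    def test_matches_explicit_scan_oracle(self, short_healthy_trip):
        rec, _ = zero_offset_correct(short_healthy_trip.depth_record)
        rec = DepthRecord(rec.times[:10000], rec.depths[:10000], 8.0)
        dives = detect_dives(rec)
        oracle = scan_detect_dives(rec.depths, rec.times)
        assert [(r.start_idx, r.end_idx)
                for r in dives.df.itertuples()] == oracle

    def test_min_depth_monotonicity(self, short_healthy_trip):
        rec, _ = zero_offset_correct(short_healthy_trip.depth_record)
        counts = [len(detect_dives(rec, min_depth=d)) for d in (15, 100, 400, 700)]
        assert counts == sorted(counts, reverse=True)

    def test_time_accounting_closes(self, short_healthy_trip):
        """Dive durations + PDIs + leading/trailing surface = record span."""
        rec, _ = zero_offset_correct(short_healthy_trip.depth_record)
        dives = detect_dives(rec).df
        total = (dives["duration_min"].sum()
                 + dives["pdi_min"].dropna().sum()) * 60.0
        lead = dives["start_time"].iloc[0] - rec.times[0]
        trail = rec.times[-1] - dives["end_time"].iloc[-1]
        assert total + lead + trail == pytest.approx(rec.span_s, abs=1.0)

    def test_recovery_against_generator_truth(self, short_healthy_trip):
        rec, _ = zero_offset_correct(short_healthy_trip.depth_record)
        detected = detect_dives(rec)
        _, dur_err, dep_err, frac = match_dives(short_healthy_trip.truth_dives.df,
                                                detected.df)
        assert frac >= 0.99
        r = np.corrcoef(detected.df["duration_min"],
                        short_healthy_trip.truth_dives.df["duration_min"])[0, 1]
        assert r >= 0.999
        assert np.median(dep_err) <= 3 * short_healthy_trip.config.noise_sd


class TestDiveStats:
    def test_triangular_dive_rates(self):
        """Descent 1 m/s to 300 m then ascent 1.5 m/s: 500 s total."""
        dt = 1.0
        down = np.arange(0.0, 300.0, dt * 1.0)
        up = np.arange(300.0, 0.0, -dt * 1.5)
        z = np.r_[0.0, down[1:], 300.0, up[1:], 0.0, 0.0]
        rec = make_record(z, dt=dt)
        row = dive_stats(rec, 0, len(z) - 2, bottom_fraction=0.999)
        assert row["duration_min"] * 60 == pytest.approx(500.0, abs=2.0)
        assert row["descent_rate_ms"] == pytest.approx(1.0, rel=0.01)
        assert row["ascent_rate_ms"] == pytest.approx(1.5, rel=0.01)
        assert row["bottom_time_min"] * 60 <= 2 * dt

    def test_square_dive_bottom_time(self):
        """10-min flat bottom at max depth, ramps kept below the 80% cutoff."""
        dt = 8.0
        ramp = np.linspace(0, 300, 10, endpoint=False)  # all < 0.8 * 400
        flat = np.full(76, 400.0)                       # 75 intervals = 600 s
        z = np.r_[np.zeros(3), ramp, flat, ramp[::-1], np.zeros(3)]
        dives = detect_dives(make_record(z, dt=dt))
        assert dives.df["bottom_time_min"].iloc[0] == pytest.approx(10.0)

    def test_sinusoidal_wiggles_counted(self):
        """Bottom oscillating between 480 and 500 m with 3 interior depth
        maxima (the profile starts and ends on a trough)."""
        dt = 8.0
        ramp = np.linspace(0, 480, 60, endpoint=False)
        tbot = np.arange(0, 600 + dt, dt)
        bottom = 490.0 - 10.0 * np.cos(2 * np.pi * 3 * tbot / 600)
        z = np.r_[np.zeros(3), ramp, bottom, ramp[::-1], np.zeros(3)]
        dives = detect_dives(make_record(z, dt=dt), wiggle_min=5.0)
        assert dives.df["n_wiggles"].iloc[0] == 3

    def test_degenerate_dive_flagged(self):
        rec = make_record([0.0, 20.0, 0.0])
        with pytest.warns(UserWarning, match="degenerate"):
            row = dive_stats(rec, 1, 1)
        assert row["degenerate"] and row["descent_rate_ms"] == 0.0


class TestExtendedSurfaceIntervals:
    def test_none_above_threshold(self):
        rec = square_dive_record(n_dives=4, surface_samples=15)  # 2-min PDIs
        count, _ = extended_surface_intervals(detect_dives(rec), 4.0)
        assert count == 0

    def test_zero_threshold_counts_all_with_successor(self):
        rec = square_dive_record(n_dives=6)
        dives = detect_dives(rec)
        count, _ = extended_surface_intervals(dives, 0.0)
        assert count == len(dives) - 1

    def test_sick_window_pdis_counted(self, sick_trip):
        day = (sick_trip.truth_dives.df["end_time"]
               - sick_trip.config.start_time) / 86400.0
        in_win = (day >= 8) & (day < 20)
        count, frame = extended_surface_intervals(sick_trip.truth_dives, 3.0)
        assert count >= in_win.sum() - 1  # all window PDIs exceed 3 min
        assert (frame["pdi_min"] > 3.0).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            extended_surface_intervals(DiveTable(), 4.0)


class TestRecordHygiene:
    def test_irregular_sampling_rejected(self):
        with pytest.raises(ValueError, match="irregular"):
            DepthRecord(np.array([0.0, 8.0, 17.0]), np.zeros(3), 8.0)

    def test_split_on_gaps(self):
        t = np.r_[np.arange(0, 80, 8.0), np.arange(200, 280, 8.0)]
        segs = split_on_gaps(t, np.zeros_like(t), 8.0)
        assert [len(s) for s in segs] == [10, 10]

    @given(hst.integers(min_value=2, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_detection_idempotent_on_surface_noise(self, n):
        """Pure sub-threshold surface noise never yields dives."""
        rng = np.random.default_rng(n)
        rec = make_record(np.abs(rng.normal(0, 0.3, 50 * n)))
        assert len(detect_dives(rec)) == 0
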