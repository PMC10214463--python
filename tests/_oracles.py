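"""Independent reference implementations used only by the tests.

These deliberately use different formulations than the package (Meeus
ecliptic ephemeris vs NOAA fractional-year series; explicit scan vs
vectorized run detection; direct kernel sums vs separable matrix products)
so agreement is a genuine cross-check.
"""

import numpy as np


def meeus_solar_elevation(unix_s: float, lat: float, lon: float) -> float:
    """Solar elevation via the Meeus low-accuracy ephemeris.

    Solar mean elements -> equation of centre -> apparent ecliptic longitude
    -> RA/declination -> hour angle from sidereal time. Accurate to ~0.01 deg,
    an independent check on the package's NOAA-series implementation.
    """
    jd = unix_s / 86400.0 + 2440587.5
    T = (jd - 2451545.0) / 36525.0
    L0 = np.radians((280.46646 + 36000.76983 * T + 0.0003032 * T**2) % 360)
    M = np.radians((357.52911 + 35999.05029 * T - 0.0001537 * T**2) % 360)
    C = np.radians((1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(M)
                   + (0.019993 - 0.000101 * T) * np.sin(2 * M)
                   + 0.000289 * np.sin(3 * M))
    true_lon = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    lam = true_lon - np.radians(0.00569 + 0.00478 * np.sin(omega))
    eps = np.radians(23.439291 - 0.0130042 * T + 0.00256 * np.cos(omega))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst = (280.46061837 + 360.98564736629 * (jd - 2451545.0)
            + 0.000387933 * T**2) % 360
    H = np.radians(gmst + lon) - ra
    phi = np.radians(lat)
    elev = np.arcsin(np.sin(phi) * np.sin(dec)
                     + np.cos(phi) * np.cos(dec) * np.cos(H))
    return float(np.degrees(elev))


def scan_detect_dives(depths, times, surface_threshold=2.0, min_depth=15.0,
                      min_duration=32.0):
    """Explicit sample-by-sample dive scan: list of (start_idx, end_idx).

    Indices are the surface samples bracketing each qualifying submergence,
    the same convention the package documents.
    """
    dives = []
    n = len(depths)
    i = 0
    while i < n:
        if depths[i] > surface_threshold:
            j = i
            while j + 1 < n and depths[j + 1] > surface_threshold:
                j += 1
            start = i - 1 if i > 0 else i
            end = j + 1 if j + 1 < n else j
            max_d = max(depths[i:j + 1])
            if max_d >= min_depth and times[end] - times[start] >= min_duration:
                dives.append((start, end))
            i = j + 1
        else:
            i += 1
    return dives


def kernel_sum_density(x, y, bx, by, x0, y0):
    """Direct Gaussian product-kernel density at a single point (x0, y0)."""
    total = 0.0
    for xi, yi in zip(x, y):
        total += (np.exp(-0.5 * ((x0 - xi) / bx) ** 2)
                  * np.exp(-0.5 * ((y0 - yi) / by) ** 2))
    return total / (len(x) * 2 * np.pi * bx * by)


def match_dives(truth_df, detected_df, max_start_gap_s=16.0):
    """Pair truth and detected dives by nearest start time.

    Returns (start_gap_s, duration_err_s, depth_err_m) arrays for the truth
    dives whose nearest detected start is within ``max_start_gap_s``, plus the
    matched fraction.
    """
    ts = truth_df["start_time"].to_numpy(float)
    ds = detected_df["start_time"].to_numpy(float)
    idx = np.clip(np.searchsorted(ds, ts), 1, len(ds) - 1)
    nearer = np.where(np.abs(ds[idx] - ts) < np.abs(ds[idx - 1] - ts), idx, idx - 1)
    gap = np.abs(ds[nearer] - ts)
    ok = gap <= max_start_gap_s
    dur_err = np.abs(detected_df["duration_min"].to_numpy(float)[nearer]
                     - truth_df["duration_min"].to_numpy(float)) * 60.0
    dep_err = np.abs(detected_df["max_depth_m"].to_numpy(float)[nearer]
                     - truth_df["max_depth_m"].to_numpy(float))
    return gap[ok], dur_err[ok], dep_err[ok], ok.mean()
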