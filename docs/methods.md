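# Methods

This note documents the models, conventions and numerical choices behind
`sealtrip`, and what its synthetic-data validation does and does not show.

## Dive-record processing

A time-depth recorder samples depth (m, positive down) at a fixed interval,
8 s by default — the resolution at which long elephant-seal deployments are
analysed. Records with sampling gaps are split into gap-free segments
(`split_on_gaps`) because a post-dive interval spanning a gap is undefined.

**Zero-offset correction.** Pressure sensors drift by metres over a
multi-month trip. The surface baseline is estimated as the 2nd percentile of
depth in consecutive windows (default 60 min), linearly interpolated between
window centres and subtracted; residual negative depths are clipped to 0. A
low percentile rather than the minimum resists negative noise spikes. The
60-min default guarantees at least one surface interval per window under a
20–40 min dive-cycle regime; with shorter windows a window can fall entirely
within one dive, making the percentile a dive depth rather than a surface
estimate. The window and percentile are parameters.

**Dive detection.** A dive is a maximal run of samples above a 2 m surface
threshold whose maximum depth reaches 15 m and whose duration reaches 32 s,
with start/end taken as the surface samples bracketing the submergence.
These thresholds are field-standard for deep-diving phocids (the shallow
threshold must clear surface swell and sensor noise; the depth/duration
floors exclude porpoising and surface activity) and are all exposed as
arguments. On records of ~10⁴ samples the vectorized detector is tested for
exact agreement with an explicit sample-by-sample scan.

**Per-dive statistics.** The bottom phase is the span of samples with depth
≥ 80% of the dive's maximum — a common convention, configurable. Descent
rate is (first bottom-phase depth − start depth)/elapsed time; ascent rate
is symmetric from the last bottom-phase sample. Wiggles — vertical
excursions during the bottom phase, a prey-pursuit proxy — are local depth
maxima with ≥ 5 m topographic prominence (`scipy.signal.find_peaks`).
Degenerate dives (< 3 samples) get zeroed statistics and a flag rather than
an error, since they occur in real records at threshold boundaries.

## Track geometry and solar position

Tracks are assumed pre-filtered (state-space filtering of raw Argos error is
a separate, solved problem) and are linearly interpolated in lat/lon at
hourly intervals; at that spacing the difference from great-circle
interpolation is negligible for a 70 km/day animal. Distances use the
haversine formula on a 6371 km sphere, checked against a
spherical-law-of-cosines implementation.

Solar elevation uses the NOAA low-accuracy series (fractional-year Fourier
series for the equation of time and declination, then the hour angle). One
refinement: the fractional-year phase runs continuously in tropical years
(365.2425 d) from 2000-01-01 rather than resetting at each civil new year —
the day-of-year convention drifts by up to ±0.75 day against the seasons
within the leap cycle, costing several tenths of a degree of declination
near the equinoxes. As implemented, the series agrees with an independent
Meeus ecliptic ephemeris to ~0.15° over 2015–2021, ample for a day/night
split. No refraction correction is applied: the 0° threshold is geometric,
and refraction shifts the terminator by well under a degree. Elevation is
evaluated at the dive start (configurable to midpoint); an elevation of
exactly 0° classifies as night — an arbitrary, documented tie-break.

## Truncated-cones morphometrics

The body is modelled as 7 circular conical frusta from ankle to ears,
divided at the 6 girth stations (radius r = girth/2π), plus a normal cone
for the head (ears→nose). The `min` variant drops the head cone, the `max`
variant adds a tail cone (ankle→tail tip); across random plausible
morphometries SA/V orders min ≤ best ≤ max because the pointed end cones add
area faster than volume. Geometry choices the measurements do not pin down,
all configurable:

- Station axial positions default to evenly spaced strictly between the ear
  (0.10 × standard length from the nose) and ankle (0.90 L) landmarks, so
  the 6 stations and 2 landmarks bound exactly 7 frusta.
- End radii at the ear and ankle are linearly extrapolated from the two
  nearest stations (floored at 0), since girths are not measured at the
  landmarks.
- Per-station blubber thickness is the mean of the dorsal and lateral
  ultrasound measurements.

The adipose fraction from geometry integrates the blubber shell (outer
radius from girth, inner radius = outer − thickness) over the frusta and
converts to mass at a lipid density of 940 kg m⁻³. Field studies calibrate
this raw fraction against isotope-dilution body water; the calibration slope
and intercept are a parameter with identity defaults, because no generally
applicable coefficients exist. All composition numbers anchored to reported
field values therefore go through `composition_split` (mass × measured
fraction, integer-kg reporting with half-up rounding) rather than through
the uncalibrated geometric fraction.

The fasting mass correction (1.2209 + 0.01329·M)·days is an empirical
onshore mass-loss rate for breeding adult females; it is added back to a
measured mass to estimate mass at departure from (or arrival at) the colony.

## Bioenergetics

Tissue energy uses standard phocid composition chemistry: lean tissue 27%
water-free at 17.99 MJ kg⁻¹ dry, lipid 90% water-free at 39.33 MJ kg⁻¹.
Field metabolic cost over a trip integrates FMR·m(t) with mass linear
between the endpoint masses; the trapezoid FMR·days·(m₀+m₁)/2 is exact for
a linear trajectory. Fever scenarios scale the 90.1 kJ kg⁻¹ d⁻¹ at-sea FMR
by (1 + p·ΔT) with p = 0.10–0.125 per °C, the range reported for
endotherms; the fever cost defaults to departure mass held constant over the
illness window (an acute illness is short against the trip's mass
trajectory), with the linear-mass alternative available. Blood volume is
20.2% of body mass at 1 kg ≡ 1 L. The fasting projection is a constant
daily rate; for a 245 kg animal at 2.37 kg d⁻¹ over 25 days it yields
59.3 kg lost and 185.75 kg remaining — the module reports the computed
final mass and makes no further adjustment.

Internal arithmetic is full precision. The reporting layer rounds the way
field tables print: decimal half-up (Python's banker's rounding would turn
90.1 × 1.5 = 135.15 into 135.1), with a pre-snap to 7 decimals to absorb
binary representation error.

## Foraging metrics

Day bins are 24-h windows anchored at trip start, not civil midnight, so day
indices match day-of-trip plots. Percent time foraging needs an operational
definition of a "foraging dive"; this package uses dives containing at least
k jaw events (default k = 1, configurable) and divides their total duration
by total at-sea time (dives + surface intervals). This is a documented
surrogate — the field literature computes the quantity from prior-work
definitions that are not fully specified — and the metric is monotone
non-increasing in k.

## Summaries

The 2-D kernel density is a Gaussian *product* kernel with per-axis Scott
bandwidths on a regular grid, checked against direct kernel sums
(`scipy.stats.gaussian_kde` is not used as the implementation because it
applies a full-covariance kernel). Day-of-trip trends use LOESS — local
linear with tricube weights (`statsmodels` lowess, default span 0.3) — with
a pointwise 95% band from 200 seeded case-resampling bootstrap replicates.
LOESS is exact on linear data, which anchors its unit test. PDI
distributions are summarized by their empirical CDF, with a zoom to the top
quantile band where extended surface intervals live.

Trip "grand means" are mean ± SD over dives within the trip; only located
dives (inside the track's time span) enter the day/night splits.

## The synthetic-trip generator

The generator is the package's validation instrument: every drawn quantity
is recorded in a ground-truth dive table before sensor corruption, so
detection, classification and summaries can be scored against truth.

A trip is a concatenation of dive cycles: constant-rate descent (1.3 m s⁻¹),
a bottom phase with whole-cycle sinusoidal wiggles (1 per bottom-minute,
15 m peak-to-trough), constant-rate ascent (1.2 m s⁻¹), then a surface
interval. Defaults emulate a healthy post-breeding trip: ~21 ± 4 min dives,
day depths 570 ± 100 m vs night 490 m (day/night judged by solar elevation
at the colony longitude — adequate because the depth regime, not the
classifier, is being driven), PDIs truncated-lognormal with mean 2.1 min and
floor 0.5 min (surface intervals are right-skewed), 1250 prey-capture
attempts per day placed uniformly in bottom phases via per-day Poisson
counts, a 0→5 m linear sensor drift and 0.2 m Gaussian depth noise —
realistic mid-range values for archival TDR pressure sensors. The track is
an hourly out-and-back correlated random walk at 70 km/day; downstream code
uses only distances and interpolation, so path realism beyond that is not
modelled.

The sick regime switches at hard day boundaries (illness windows are
reported day-indexed): on days [8, 20) PDIs are drawn log-uniformly from
3–30 min and daily jaw events drop to 250; after the window each PDI is
replaced with probability 0.01 by a 30–200 min draw; dive duration carries a
−0.07 min/day linear trend from a 19 min mean, and paired morphometry
encodes a 294→245 kg trip with blubber thinning. The trend field is the one
generator parameter without a healthy-trip counterpart; it exists because a
declining duration trend is a diagnostic the summaries must recover.

None of the distributional forms (trapezoid dives, lognormal PDIs, Poisson
event counts) is claimed to be the true generative process of seal
behaviour — the field data do not identify one. Passing tests show the
*pipeline* recovers known structure under realistic noise, drift and rates;
they do not validate the forms themselves, and no acceptance check depends
on a form beyond its range and rate.

## Problem sizes and determinism

The validation suite uses an 80-day trip (~4,900 dives, 864,001 samples at
8 s) for detection recovery, 25-day seed-paired trips for sick/healthy
discrimination, 1,000-point space-time grids for the solar cross-check and
1,000 random morphometries for geometry ordering — sizes at which every
statistic is stable across seeds while the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; fixed seeds give bit-identical trips.

## Known limitations

- Haul-out periods, 3-D movement, prey fields and accelerometer waveforms
  are not simulated; jaw events are consumed as timestamps.
- Antimeridian-crossing tracks are not supported (linear lon interpolation
  would wrap incorrectly).
- The geometric adipose fraction is uncalibrated by default and should not
  be compared directly to isotope-dilution body composition without a
  study-specific calibration.
- Dive-shape classification (drift/transit/foraging typology) is out of
  scope; bottom-phase statistics are computed for all dives alike.
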