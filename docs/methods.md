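# Methods

## Model

`ecoclimex` implements a CLIMEX-style semi-mechanistic bioclimatic model.
The year is exactly 52 weeks of 7 days (364 days; the leftover calendar
day is absorbed by the last week).  For each grid cell and week *w* the
engine computes:

* **Temperature index** `TI_w`: a piecewise-linear trapezoid over the
  four-point response `(DV0, DV1, DV2, DV3)` evaluated at the weekly mean
  temperature `tavg_w = (tmin_w + tmax_w)/2` — 0 at or below `DV0` and at
  or above `DV3`, 1 on `[DV1, DV2]`, linear ramps between.
* **Moisture index** `MI_w`: the same trapezoid form over
  `(SM0, SM1, SM2, SM3)` evaluated at soil moisture `S_w` (fraction of
  bucket capacity).
* **Diapause indicator** `DI_w ∈ {0, 1}`: winter diapause is induced at
  the first week of the shortening-day half of the year with day length
  below `DPD0` and `tavg` below `DPT0`, and terminated at the first
  subsequent lengthening-day week with `tavg` above `DPT1` after at least
  `DPD` days of diapause development (`DPD = 0` makes termination
  instantaneous).  The 52-week state machine is run twice so the reported
  year is the periodic steady state — an alpine cell enters January
  already dormant.  Summer diapause (`DPSW = 1`) is not implemented.
* **Growth index** `GI_w = TI_w · MI_w · DI_w`, and annually
  `GI_A = 100 · mean(GI_w)`.
* **Stress indices** (cold, heat, dry, wet, hot-wet): linear accumulation
  of weekly threshold exceedance at the species' weekly rates, scaled to
  0–100 and capped at 100, e.g.
  `CS = min(100, Σ_w 100·|THCS|·max(0, TTCS − tmin_w))`.  Cold stress
  reads the weekly minimum, heat stress the weekly maximum, dry/wet
  stress the soil moisture, and hot-wet stress the mean temperature
  gated by a moisture threshold.  Exponential stress compounding used by
  some proprietary engines is deliberately not reproduced: in the
  temperate-alpine regime this package targets, all stress totals are
  zero, so the compounding choice is immaterial, and the linear rule is
  directly testable against single-week closed forms.
* **Degree days and voltinism**: `DD_w = 7 · max(0, tavg_w − DV0)`,
  `DD_annual = Σ DD_w`, `generations = DD_annual / PDD` (real-valued;
  area statistics use `generations ≥ 1` and `≥ 2`).  No within-day
  sinusoidal integration is attempted — monthly-mean inputs do not
  support it.
* **Ecoclimatic Index**:
  `EI = GI_A · Π_s (1 − stress_s/100)`, set to 0 when
  `DD_annual < PDD` (the growing season cannot complete one generation),
  clamped to [0, 100].  A location is *suitable* above EI 5, *highly
  suitable* above EI 15; below EI 1 the species cannot persist.  The
  preoviposition degree-day requirement of overwintered females is
  intentionally not subtracted from `PDD`, matching the published
  parameterization this package defaults to.

The default species parameters are the published fit for
*Halyomorpha halys* (brown marmorated stink bug): development between
12 and 33 °C with optimum 27–30 °C, 595 degree days above 12 °C per
generation, winter diapause induced below 12 h day length and 5 °C.  Two
of the printed hot-wet labels are transposed in the published table
(28 appears as a "soil moisture" and 1.5 as a "temperature"); on
dimensional grounds the package stores `TTHW = 28 °C` (temperature
threshold) and `MTHW = 1.5` (moisture threshold).  Negative printed
rates (`THCS`, `HDS`) are stored as printed for round-trip fidelity; the
engine uses their magnitudes.

## Soil moisture

A single-bucket weekly water balance:
`S_w = clip(S_{w−1} + (rain_w − E_w)/capacity, 0, s_max)`, iterated over
repeated 52-week passes (up to 20, tolerance 1e−9) to its periodic
steady state, so results are independent of the spin-up start wherever
the trajectory touches a bound.  Weekly evaporative demand is
`E_w = k_e · 7 · max(0, tavg_w) · (1 − (rh09_w + rh15_w)/200)`, with
`k_e = 0.8` mm·°C⁻¹·day⁻¹.

Defaults: capacity 100 mm and `s_max = 1.0` — the classic convention
that water beyond field capacity runs off.  This cap matters: the
species' wet-stress and hot-wet thresholds sit at 1.5 × capacity, i.e.
above anything a runoff-limited bucket can store, which is why wet
stress never materializes in temperate-alpine climates (any climate with
a sustained annual surplus would otherwise pin the bucket above the
threshold and accrue spurious wet stress in its steady state).  Setting
`s_max` above 1 (e.g. 2.0) represents ponding and makes those thresholds
reachable; the stress formulas themselves are exercised at such values
in the unit tests.

## Monthly → weekly conversion and derived drivers

* Temperatures (and the derived humidities) are interpolated piecewise-
  linearly from month midpoints (day-of-year anchors of a non-leap
  365-day calendar) to the 52 week midpoints, with periodic wrap; the
  364/365-day mismatch is absorbed at the year boundary.
* Precipitation is disaggregated proportionally to the number of each
  month's days falling in each week (the 52nd week spans 8 days), so
  annual totals are conserved exactly.
* Relative humidity at 09:00 and 15:00 is derived from the temperature
  extremes alone: dew point ≈ daily minimum, so actual vapour pressure is
  `e_s(tmin)` with the Magnus form
  `e_s(T) = 6.112·exp(17.62·T/(243.12 + T))` hPa, and the 09:00/15:00
  air temperatures sit at fixed fractions 0.4 and 0.9 of the diurnal
  range above `tmin`.  The fractions are a completion choice — standard
  practice when vapour-pressure observations are absent — not a
  reconstruction of any particular observation network.
* Day length uses the standard solar-declination formula
  `δ = 23.44°·sin(2π(284 + doy)/365)`,
  `daylength = (24/π)·arccos(−tan φ · tan δ)`, at each week's middle
  day; valid equatorward of the polar circles.

## Scenarios

Delta-change construction: monthly temperature deltas (°C) are added to
both `tmin` and `tmax` (diurnal range unchanged), monthly precipitation
deltas (%) scale the sums multiplicatively (deltas must stay above
−100 %, so negative precipitation is impossible by construction).
Humidity is re-derived from the perturbed temperatures.  Interannual
variability is untouched by construction — the delta method operates on
30-year mean monthly signals.  Uniform signals are applied everywhere;
per-cell signal grids must match the baseline layout exactly (no
resampling is performed).

## Synthetic study conditions

The generator emulates an alpine country so the full pipeline runs
without proprietary gridded climatologies:

* **Topography**: a warm valley floor (250 m) with two smooth diagonal
  Gaussian ridges (a lower northern range ~1150 m, a higher southern
  massif up to ~2300 m) plus 25 m Gaussian roughness.
* **Temperature**: sea-level annual mean 13 °C with a 9 °C-amplitude
  sinusoidal seasonal cycle peaking in July, lapse rate −6.5 °C·km⁻¹,
  diurnal range 8 °C, monthly Gaussian noise (σ = 0.3 °C).  These values
  place the low-elevation cells near the observed climate of
  north-alpine lowland towns (annual mean ≈ 9–11 °C, ≈ 1.3–1.6
  generations per year) and keep all weekly temperatures strictly inside
  (−18, 33) °C, so no cold or heat stress accrues anywhere.
* **Precipitation**: scaled to twice the cell's own monthly evaporative
  demand plus a 10 mm/month base (an optional orographic term is off by
  default).  With the runoff-capped bucket this pins soil moisture at
  field capacity — inside the moisture plateau — so moisture is
  non-limiting and dry/wet/hot-wet stress is zero, which is precisely
  the regime reported for temperate-alpine climates: suitability there
  is set by temperature and the degree-day budget alone.  The generator
  therefore does **not** emulate realistic precipitation fields
  (orographic gradients, drought years); tests passing on synthetic data
  say nothing about moisture-limited range edges, and the moisture
  pathway is instead exercised directly in unit tests.
* **Occurrences**: points are sampled from cells with probability
  proportional to `max(0, EI − 5)` with uniform within-cell jitter, so
  sampled records sit in suitable cells by construction (overlap
  fraction 1.0 is a consistency check of the overlay machinery, not a
  validation of the science).
* **Extent**: 20 × 15 cells of 0.02° for desk-scale work; the
  `swiss_size` preset uses 101 × 111 = 11,211 cells, the size of the
  national 2-km grid the reported area percentages refer to.

Everything is driven by one explicitly seeded generator per call; no
global random state.

## Numerical choices

* Cell membership for point queries is half-open,
  `[center − Δ/2, center + Δ/2)`: a point on a shared edge belongs to
  the cell whose lower edge it is.  Records landing on masked (water)
  cells are snapped to the nearest land cell within one cell width.
* Suitability classification uses strict inequalities at 5 and 15 and
  the survival cutoff at 1; area percentages are computed over all land
  cells (alpine cells included) and rounded only at presentation (EI to
  integers, generations to 2 decimals, weeks to integers in the
  location tables).
* Growth windows are the span from first to last week with `GI_w > 0`;
  mid-season zero dips are ignored.  Phenology shifts are signed so that
  positive means earlier spring start / later autumn stop.
* Weekly interpolation can nick `tmin ≤ tmax` by rounding when the
  diurnal range varies between months; the weekly `tmax` is floored at
  the weekly `tmin`.
* The occurrence CSV writer uses 17-significant-digit floats and the
  readers use round-trip float parsing, so file round-trips are exact.

## Limitations

* Only winter diapause is implemented; `DPSW = 1` raises.
* The moisture machinery is deliberately simple (one bucket, no snow,
  no irrigation); in climates where moisture limits the range the EI
  will be only as good as that bucket.
* GeoTIFF I/O is not provided; gridded I/O is NetCDF (scipy backend,
  NETCDF3) and long-format CSV.
* Reproducing the published national numbers requires the proprietary
  2-km climatology and change-signal grids; the packaged reported area
  percentages support fold-change arithmetic and comparisons, not
  re-simulation.
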