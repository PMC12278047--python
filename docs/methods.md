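# Methods

This note describes what `seastress` computes and why the pieces are built
the way they are. It is written for a reader who knows basic climate
statistics but has not read the source.

## 1. Problem

Marine organisms experience ocean warming and acidification partly through
*extreme days*: days on which sea-surface temperature (SST), hydrogen-ion
concentration (H+), surface pCO2 or aragonite saturation state (Ωa) crosses
a threshold. How many extreme days a projection produces depends at least
as much on *how the threshold is defined* as on the projection itself. The
package implements the main competing definitions side by side so their
consequences can be compared on identical inputs:

- **Seasonally constant (SC) vs seasonally varying (SV)** percentile
  thresholds: one percentile of all days per cell, versus a percentile
  anomaly added to the mean seasonal cycle so that extremes can occur in
  any season.
- **Fixed vs adaptive baselines**: a static historical reference period
  (1975–2014 by default), versus a rolling window of the preceding
  *N* = 100 years, representing gradual organismal adaptation.
- **Absolute thresholds** with direct physiological meaning: Ωa < 1
  (corrosive), Ωa < 3 (reef habitat suitability), pCO2 > 1000 μatm
  (environmental hypercapnia).
- **Degree heating weeks (DHW)**, the standard coral thermal-stress
  accumulation metric.

Because daily Earth-system-model output is large and external, the package
ships a **synthetic scenario generator** whose statistical structure
(seasonal cycle, red noise, secular trends that diverge across emission
scenarios) is sufficient to exercise every diagnostic. The generator's
defaults *are* the study conditions for the acceptance checks; they were
chosen a priori from closed-form reasoning, not tuned to outcomes.

## 2. Calendar and grid conventions

All fields live on a 365-day "noleap" calendar. Time is stored as decimal
years, `year + (doy − 0.5)/365` for daily data and the month-midpoint
equivalent for monthly data. Fields are `xarray.DataArray`s with dims
`(time, lat, lon)` and auxiliary integer coordinates (`year`, `doy` or
`month`); they round-trip through netCDF (`NETCDF4_CLASSIC`). Global
statistics are area-weighted with cos(latitude) weights, renormalized over
non-NaN cells.

## 3. Synthetic generator

Each variable is generated per cell as

```
value(t, lat) = mean(lat) + trend(t; scenario) + seasonal(doy, lat, t)
              + coupling · sst_anomaly(t) + AR(1) noise
```

- `mean` and `seasonal_amplitude` are linear profiles in |lat|/90 between
  an equatorial and a polar value; the seasonal phase peaks at day 196
  (mid-July) and is antiphased in the southern hemisphere.
- `trend` is flat before 1950, linear at `base_rate` per decade until the
  divergence year 2040, and then scenario-dependent: `historical`/`linear`
  continues the line, `mitigation` relaxes exponentially onto a plateau
  (slope-continuous at 2040), `high` adds a quadratic acceleration.
- Noise is AR(1) (`scipy.signal.lfilter`) with lag-1 correlation ρ and
  stationary standard deviation `noise_sd`; the innovation variance is
  `sd²(1 − ρ²)`.
- OA variables carry a `coupling` term onto the SST noise anomaly so that
  Ωa is anticorrelated with temperature, as observed.

Random streams are drawn from `numpy.random.SeedSequence` with spawn keys
`(variable index, stream)`. Streams do not depend on the scenario label,
so `mitigation` and `high` are **bitwise identical before 2040** — the
analogue of scenarios branching from a shared historical run.

Monthly archives (1850–2100 by default) are hybrids: on years where daily
output exists they are exact calendar-month means of the daily field; on
other years they are generated directly at monthly resolution with the
matching AR(1) parameters (`ρ_monthly = ρ^(365/12)`, variance from the
closed-form monthly-mean formula). This keeps daily/monthly consistency
exact without simulating 251 years of daily data.

Default per-variable parameters (per cell): SST mean 28→−2 °C
equator→pole, amplitude 1→6 °C, trend 0.15 °C/decade, ρ = 0.85,
σ = 0.4 °C; H+ mean 6.8 nmol/kg, trend 0.06 nmol/kg/decade; pCO2 mean
280 μatm, trend 15 μatm/decade, amplitude 10 μatm growing 0.03/decade
fractionally; Ωa mean 4.0→1.6, trend −0.07/decade, ρ = 0.9, σ = 0.04,
coupling −0.05 per °C. The default grid is 10 × 20 (6.3°-ish spacing),
daily years 1975–2014 and 2061–2100.

What the generator does **not** emulate: spatial correlation of noise,
ENSO-like interannual modes, sea ice, carbonate-chemistry consistency
between H+, pCO2 and Ωa (each is generated marginally apart from the
shared SST coupling), and any circulation dynamics.

## 4. Thresholds

- **Fixed SC**: per-cell `np.percentile` (linear interpolation) over all
  reference days; 95th for upper-tail variables (SST, H+, pCO2), 5th for
  the lower tail (Ωa). Exceedance is strict (`>` / `<`).
- **Fixed SV, binned**: pool days into 5-day day-of-year bins across the
  reference years, take the percentile per bin, then smooth circularly
  with a Gaussian (σ = 10 days, truncated at 4σ).
- **Fixed SV, anomaly**: smoothed day-of-year climatology plus a single
  percentile of the pooled anomalies. The two SV variants agree when the
  noise is homoscedastic; they differ when variance has a seasonal cycle.
- **Adaptive SC**: the mean over the preceding 100 years of the annual
  maximum (or minimum, for the lower tail) of monthly means, AMM_max /
  AMM_min. The AMM of a seasonal series sits near a fixed percentile of
  the daily distribution — see below — so this is a percentile threshold
  in disguise, computable from monthly archives alone.
- **Adaptive SV**: the historical SV threshold plus the change in monthly
  climatology between the rolling window and the historical reference,
  interpolated to day of year linearly through month midpoints with
  periodic wrap.

Windows exclude the target year (`[target − N, target − 1]`) and an
archive too short for the full window raises rather than silently
shortening.

### The AMM ≈ 93rd-percentile identity

For a pure sinusoid sampled on a 365-day year and averaged within calendar
months, the annual maximum monthly mean falls at a fixed percentile rank
of the daily values, independent of amplitude. Sweeping the phase offset
over the 365 integer days gives rank mean 93.40, minimum 90.41, maximum
95.34 (and the mirror image ≈ 6.6 for AMM_min). `calibrate_amm_percentile`
confirms this empirically: on the default synthetic fields the
RMSE-minimizing integer percentile matching the AMM is 93 (max mode) and
7 (min mode).

## 5. Coral metrics

The maximum monthly mean (MMM) is the warmest month of a *detrended*
monthly climatology: an ordinary-least-squares trend is removed per cell
with the series re-centred at pivot year 1988.2857 before the month-wise
means are taken. The hotspot is H = SST − MMM; DHW on day *d* is

```
DHW(d) = (1/7) · Σ_{k=d−83..d} H(k) · 1{H(k) ≥ 1 °C}     [°C-weeks]
```

an 84-day (12-week) inclusive trailing accumulation. Useful closed forms:
steady H = 2 gives DHW = 24 after spin-up; a 7-day H = 1 excursion peaks
at DHW = 1; H ≡ 0.9 accumulates nothing. Days with DHW > 4 are counted as
coral thermal extremes. The counting rule `count_rule="le"` (accumulate
H < 1 °C instead) is provided as a switch for sensitivity checks against
variant wordings of the rule; the default is `"ge"`.

## 6. Events and scenario comparison

- **Compound events**: day-wise intersection/union of extreme-day masks on
  identical grids/time axes.
- **Detrended percentile change**: percentiles of each period after
  removing the period's own OLS trend about its midpoint, so a pure shift
  between periods is recovered exactly and any midpoint-anchored linear
  trend leaves the statistic unchanged.
- **Joint distributions**: area-weighted 2-d histograms of two percentile
  fields; a coverage region is built greatest-density-first (a highest
  density region); overlap between periods is the Jaccard index of their
  regions on shared bins.
- **Site reports**: per-site fractions of days extreme in only one
  stressor, both, or neither, for named locations snapped to the nearest
  grid cell.

The headline scenario comparison is the area-weighted global-mean percent
of extreme days. Under **adaptive** thresholds, the mitigation scenario's
end-of-century value is closer to the historical value than to the
high-emission value for all four variables; under **fixed** baselines the
OA variables saturate (mitigation ≈ high ≈ 100%), because the secular
trend dwarfs the historical envelope. This contrast is the package's
central qualitative result and is asserted in the acceptance tests.

## 7. Numerical choices

- `np.percentile(..., method="linear")` everywhere; strict inequalities
  for exceedance, so a value exactly at the threshold is not extreme.
- Circular Gaussian smoothing via `scipy.ndimage.gaussian_filter1d`
  (`mode="wrap"`, σ = 10 days, truncate 4σ).
- Rolling-window means via cumulative sums (O(1) per window).
- DHW via cumulative sums of the qualifying-hotspot series; partial
  windows at the start of a record are computed from the days available.
- Deterministic seeding throughout; re-running the pipeline with the same
  config and seed reproduces bit-identical mask files.

## 8. Problem sizes

The test suite runs on the default 10 × 20 grid with 40-year daily periods
(generation of all three scenarios ≈ 15 s) plus single-cell closed-form
cases; the pipeline tests use a 2 × 3 grid. Memory stays well under one
variable-scenario of daily data (~23 MB at default size).

## 9. Limitations

Synthetic fields are statistically, not dynamically, realistic; absolute
values of the headline percentages depend on generator parameters and
should be read qualitatively. Only the ordering claims, closed forms and
invariances are asserted quantitatively. No significance testing of
changes is performed, and no map rendering is included.
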