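# Methods

This note documents the models and procedures implemented in
`specimentrends`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
affect reproducibility.

## Record filtering

Validity filtering keeps records with a non-empty species string (after
whitespace trim — no taxonomic name resolution) and a collection year in
[1800, 2024], optionally restricted to a basis-of-record value
(case-insensitive, default `PreservedSpecimen`). Spatial analyses
additionally require both decimal coordinates present and in physical
range; (0, 0) and low-precision coordinates are deliberately retained,
since the filters are about presence and validity, not plausibility
heuristics. Non-spatial metrics always run on the full valid set, so
location coverage (the percentage of valid records with coordinates) is a
reported property of the data, not a filter side effect. Unparseable years
or coordinates degrade to missing values with a counted warning rather
than aborting: large aggregated downloads always contain malformed rows.

`location_coverage` and `decline_percent` return exact (unrounded) values
so that their algebraic identities hold (`coverage == 100` iff every record
has coordinates; `decline + 100·recent/peak == 100`); one-decimal rounding
happens at the reporting layer.

## Yearly metrics and peak/decline quantification

Annual series are computed on a zero-filled year grid inside the analysis
span (default 1950–2019): years with no records count as zero for moving
averages and period means. Zero-filling is a documented choice — on sparse
early series it pulls window means down, but it keeps window arithmetic
well-defined and period means comparable.

Grid cells are half-open floor cells `[d, d+1)` in each coordinate, with
+90° latitude clamped into row 89 and +180° longitude into column 179, so
every valid point maps to exactly one of 180 × 360 = 64,800 cells.

Moving-average windows are labelled by their inclusive year span; the peak
window maximises the w-year mean with ties broken toward the earliest
start year (determinism; any other rule would be arbitrary). The change
map divides by the full period length in years — including zero years — in
both the recent and reference periods, because "mean annual count" is
defined over a fixed period, not over years-with-records.

LOESS is a tricube-weighted local polynomial regression (default span 0.3,
degree 2, fitted at each observed year over the nearest `ceil(span·n)`
points). It is implemented in-package because the local-regression degree
is a first-class parameter here, and it is display-only: no peak, decline
or forecast consumes smoothed values.

## Anomaly screen

The unit of screening is the (institution, collection-year) record count.
Counts are log-transformed with the natural log; the base is irrelevant to
flagging (it rescales both sides of the threshold comparison identically)
but fixes the scale on which z-scores are reported. Two z-scores are
computed per cell, both with sample (n−1) standard deviations:

* `z_within`: against the same institution's counts across all its years;
* `z_across`: against all institutions' counts within the same year.

A cell is flagged iff **both** exceed `k` (conjunctive, one-sided: only
disproportionately large counts are anomalies here). A z-score is
undefined — and can never flag — when its comparison group has fewer than
`min_group = 3` members or zero spread; standard deviations over one or
two points carry no information. Records with no institution code are
pooled under a reserved label and exempted: they have no comparison group.
The linear-scale departure (linear z across institutions within the year)
is attached to the removal report as a diagnostic but never used for
flagging.

Filtering is single-pass: flags are computed once and the flagged cells'
records removed. Z-scores are *not* recomputed on the cleaned set; an
iterated filter would have different (and harder to reason about)
semantics. Defaults: `k = 3.0`; named presets `snapshot-chordata` /
`snapshot-plantae` (3.1) and `snapshot-arthropoda` (3.6) for the noisier
historical-snapshot data.

## Snapshot accrual forecasting

For each collection year, the record count observed at successive annual
database snapshots forms a short time series (17 points for 2007–2023).
Series construction aggregates institutions, imputes zeros only before the
year's first non-zero snapshot (the year had not yet appeared), linearly
interpolates interior gaps (ARIMA needs regular spacing), holds the last
value for trailing gaps, and marks every imputed point.

Models are ARIMA(p, d, q) with no seasonal terms. Estimation is maximum
likelihood via statsmodels' state-space ARIMA; order selection is an
exhaustive grid over p, q ∈ [0, 2] at fixed d, minimising the
small-sample-corrected Akaike criterion

```
AICc = −2·llf + 2k + 2k(k+1)/(n − k − 1)
```

with k the number of estimated parameters and n the effective sample size
after differencing. The exhaustive grid (rather than a stepwise search) is
deliberate: at 9 candidates per series determinism costs nothing.
Candidates that fail to converge or have undefined AICc are excluded; if
none survive, the model falls back to ARIMA(0, d, 0) with a warning.
Models with d ≥ 1 carry no deterministic trend term; d = 0 models include
a constant.

Forecasts use the model recursion with normal-theory 95% intervals
(mean ± 1.959964·SE). Negative means are reported as computed, with a
separate zero-floored display value. For ARIMA(0,1,0) this reduces to the
random-walk closed form — flat forecast at the last value, SE = σ√h —
which the tests verify to 1e−8.

The differencing order is chosen by in-sample validation: fit on snapshots
up to an explicit cutoff, forecast the held-out snapshots at the requested
horizons, pool RMSPE across collection years per horizon, and pick the d
minimising the mean RMSPE across horizons. The cutoff is a required
parameter rather than a default because with 17 snapshots the train/test
split materially changes the comparison.

## Synthetic scenarios and what they show

The generator is the test bed: it produces data with the structures the
pipeline must detect, with exact ground truth.

* Effort: piecewise-exponential rise/fall around a peak year (defaults
  rise 0.03/yr, fall 0.02/yr, peak 1980 — the fall rate roughly halves
  effort over 35 years, comparable to the declines of interest).
* Institutions: 20 by default, log-normal scales (median 30 records per
  effort unit, log-SD 1), each with a home coordinate and 5° normal
  scatter; per-cell counts Poisson(scale × effort). The default scenario
  yields ~45k records over 1950–2019.
* Species: 300-species pool with log-series abundance weights (p = 0.995).
* Anomalies: multiplicative spikes replicate a cell's records to
  `round(multiplier × n)` rows.
* Snapshots: record appears at `max(onboarding year, collection year +
  geometric lag)` (p = 0.5, mean lag 1 year), onboarding uniform over
  1990–2015; optional removal events drop a random fraction of present
  records.

Ground truth (expected yearly series, peak window, decline, anomaly keys,
per-year asymptotes) is computed from the realised institution scales and
the deterministic effort curve using the same definitions the pipeline
applies to data.

What passing these tests shows: the pipeline recovers peaks, declines,
injected anomalies and accrual asymptotes when the data actually contain
them under Poisson/log-normal noise. What it does not show: robustness to
real-data pathologies the generator omits — taxonomic name drift,
coordinate errors, institution splits/merges, effort curves with multiple
peaks, non-stationary species pools, or duplication patterns subtler than
single-cell spikes.

Experiment sizes (200 anomaly replicates, 1000 peak-scan series, 500
AR-recovery replicates, 100 coverage replicates, 50 validation scenarios,
100 end-to-end replicates) are the package's fixed reference experiment
definitions, chosen to make the pass/fail margins statistically meaningful
while keeping the whole suite re-runnable in minutes on one CPU.

## Numerical conventions and edge cases

* Sample standard deviations (n−1) everywhere.
* Peak-window ties → earliest window; AICc ties → fewer parameters, then
  lower p.
* Zero-amplitude effort is allowed and yields an empty record set (the
  ground-truth decline is then undefined and reported as NaN).
* All simulation randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical seeds give
  byte-identical datasets.
* CLI exit codes: 0 success, 2 configuration error, 3 data error.

## Known limitations

* The anomaly screen detects single-cell spikes only; coordinated
  duplication spread across many institution-years (or below-background
  anomalies) will pass.
* Snapshot series shorter than d + 3 points cannot be fitted and are
  skipped (counted in reports).
* The unique-species metric trusts the species string; synonymy inflates
  it and lumping deflates it.
* Continent/grouping splits are generic group-by parameters; no
  country-to-continent authority is bundled.
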