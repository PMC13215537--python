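# Methods

This note documents the models and procedures `dredgecarbon` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic test suite can show.

## Carbon-disturbance model

Disturbed organic carbon for one extraction event is

    C = M × (TOC / 100)

with `M` the sediment mass removed (kg) and `TOC` the total organic carbon
content of that sediment in percent of dry weight. "Disturbance" here means
the organic carbon contained in sediment that is mechanically removed or
re-exposed; the (smaller) fraction actually remineralised to CO₂ is out of
scope, as is the fate of dredge spoil after disposal at sea.

Neither `M` nor `TOC` is known exactly. `TOC` is never measured for the
extracted sediment itself, so it is treated as a random draw from an
empirical pool of measurements taken in comparable sediments; `M` is known
for most modern records but must be imputed for many historical ones. The
Monte Carlo engine propagates both sources of uncertainty jointly.

## Record harmonisation

* **Units.** Long tons (1016 kg — the "ton" of 19th-century UK returns),
  metric tonnes (1000 kg), m³ and cubic yards (0.764554858 m³) are all
  accepted; a source must declare which ton it uses, since the two differ by
  1.6%. Volumes convert at a single configurable wet bulk density, default
  1700 kg/m³, because sediment type and dry bulk density are typically
  absent from the records that need the conversion.
* **Annualisation.** A period record's mass is divided equally across its
  years as real numbers (no rounding), so the annual masses sum back to the
  reported total exactly. A period record with *no* usable quantity is kept
  as a single period-level imputation event: the imputation model is fitted
  on per-works masses, so drawing once per works and annualising afterwards
  is the consistent order of operations.
* **Exclusions.** Records tagged with commodity categories lacking any TOC
  characterisation (maerl; historical non-aggregate categories such as tin
  prospecting, clay, shingle, boreholes) are dropped with an audit trail —
  every input record lands in exactly one of (retained, audited). The
  sparse-year rule drops shelf-scale (industry, year) cells with fewer than
  2 contributing countries, since a single-nation year would masquerade as a
  shelf total; it applies only to national/licence-scope annual series, not
  to the port-level historical block, which is a single-country analysis by
  design.

## Mass imputation

Two stages, mirroring how record quality degrades with age:

1. **Cost conversion.** An average cost per kg is calibrated on the records
   reporting both cost and quantity. The default estimator is the unweighted
   mean of per-record cost/mass ratios; total-cost/total-mass is available
   as a config switch (the two differ when works vary in scale — with six
   calibration records there is no strong basis to prefer either, so the
   choice is surfaced rather than hidden). No currency deflation is applied
   across the calibration window; a single rate is used, which is a known
   simplification.
2. **Log₁₀-normal model.** All estimable masses (reported + cost-derived)
   are log₁₀-transformed; the model stores their mean and sample SD (n−1)
   plus a Shapiro–Wilk W and p on the log scale. The Shapiro–Wilk result is
   descriptive — it is always reported but never gates the model, because a
   non-significant test on n ≈ 60 is weak evidence either way and the
   log-normal family is independently motivated (positive, right-skewed
   masses spanning orders of magnitude). Draws are 10^N(μ, σ), strictly
   positive. Fits on fewer than 3 masses are refused; σ = 0 fits are flagged
   degenerate. scipy's Shapiro–Wilk implementation is used and is
   cross-checked in the test suite against values computed independently
   with R's `shapiro.test` on five fixed datasets.

## %TOC pools

A "distribution" is the empirical pool itself: draws resample the observed
values uniformly with replacement. No kernel smoothing and no parametric fit
are applied — resampling reproduces the pool's percentiles without extra
assumptions, and the pools are large enough (10²–10⁴) that discreteness is
immaterial. Consequences: draws can never leave the observed range, and
values of exactly 0.0 %TOC are legal and retained.

* **Coastal pool** (port dredging): subtidal samples (`subtidal_other`)
  below mean high water within 5 km of the coastline. Seagrass and
  saltmarsh samples are excluded because vegetated-habitat sediments are
  unrepresentative of dredged channels and berths. The 5 km cut-off is a
  closed interval (a sample at exactly 5 km is retained). Distance is
  planar Euclidean in the projected CRS; at ≤5 km the difference from
  geodesic distance is negligible.
* **Substrate pools** (aggregates): point-in-polygon assignment of samples
  to sand / coarse / mixed substrate-map classes. A point on a shared
  boundary goes to the first covering polygon in map order (deterministic
  tie-break); points covered by no polygon are classed `other` and excluded
  from the pools. Invalid polygons abort classification with the polygon id.
* **Combined pool** (untyped aggregate records): the default pools all raw
  values, so class weights are implied by sample counts. An explicit
  weighted mixture (e.g. 53/46/1) is available; the sensitivity sweep
  exists precisely because that choice is the main modelling assumption for
  pre-1991 records, and it shows the estimate varies smoothly and modestly
  between the pure-class endpoints.

All geometry is handled with shapely in a single projected equal-area CRS in
metres (LAEA-style). The package does not reproject: inputs must arrive
projected, which is the normal state of curated national/shelf datasets.

## Monte Carlo engine

* **Draw scope.** Default `per_record`: each event gets its own %TOC draw
  each run, which treats events as independent sediments (narrower bands).
  `per_year_total` shares one draw across a scope-year (wider bands,
  appropriate if one believes a year's works hit correlated sediment). Both
  are implemented; the default is the less conservative reading and the
  difference is visible in the test suite.
* **Imputed masses** are redrawn every run by default (uncertainty in M
  propagates into the bands); a fix-once option freezes one draw per record
  for scenario-style runs.
* **Seeding.** One master seed spawns an independent substream per scope
  group, keyed by a stable hash of (industry, country, site, year). A
  country simulated alone therefore reproduces bit-identically its slice of
  a joint shelf run, while shelf totals remain exact run-by-run sums of
  country totals. Aggregation to shelf (from countries) and to nation (from
  ports) sums retained run-total vectors, then recomputes mean, SD (n−1)
  and percentiles on the summed vector.
* **Percentiles** use linear interpolation between order statistics
  (numpy's default), stated here because percentile conventions differ
  across environments.
* **Convergence.** The diagnostic repeats independently-seeded simulations
  (default 10 iterations) over an ascending grid of run counts and reports
  the inter-iteration SD of the grand mean; "stabilised" is operationalised
  as relative inter-iteration SD < 1%. With the default pools the output
  stabilises well before 10,000 runs, which is retained as the production
  run count.
* **Units.** kg internally; megatons (1 Mt = 10⁹ kg) in all user-facing
  summaries.

Multi-year headlines ("X ± Y Mt C/yr over a range") are the mean and n−1 SD
of the per-year mean estimates — i.e. Y measures between-year variability.
A pooled run-level SD (pure simulation uncertainty) is computed behind a
flag, because the two answer different questions and either could be meant
by a "±" in prose.

## Synthetic study world

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions of a Northwest-European-Shelf-scale
analysis:

* **%TOC pools** are lognormal — right-skewed, strictly positive, median
  well below the mean, as observed in shelf sediments — parameterised from
  (median, 95th percentile) by quantile inversion: coastal (1.78, 6.46) at
  n = 9920; sand (0.46, 5.07) at n = 7262, coarse (0.58, 5.8) at n = 720,
  mixed (0.85, 6.5) at n = 273. The class-level targets were solved
  numerically so that the count-weighted pooled distribution has median
  ≈ 0.48 and p95 ≈ 5.19; the class shapes themselves are otherwise
  unconstrained by published summaries. A two-parameter lognormal cannot
  simultaneously match a heavy left tail (the implied coastal p5 is ≈ 0.49,
  higher than real coastal pools exhibit), which slightly *narrows* the
  lower band and is a known difference from real data.
* **Decoys**: every exclusion rule gets a dedicated batch (seagrass,
  saltmarsh, above-MHW, beyond-5-km) drawn from the same law as the clean
  pool, so each filter's effect is independently assertable by count.
* **Geometry**: a straight coastline along y = 0 with a sand/coarse/mixed
  checkerboard beyond 6 km. No attempt is made to mimic real shelf
  geography; the geometry exists to exercise distance and overlay logic
  with exactly known truth.
* **Event tables**: annual sediment-removal totals of 93.7 Mt/yr (port
  dredging, 1995–2021, between-year CV 0.40) and 27.4 Mt/yr (aggregates,
  1955–2022, CV 0.70, non-UK countries entering in 1972, sediment types
  assigned 53/46/1 from 1991 and unknown before). Because the emulated
  record is one *fixed* historical series whose period mean and spread are
  stated conditions — not a super-population to be sampled — the annual
  factor series is conditioned: log-factors are standardised to exact
  (mean, SD) and the series rescaled to unit mean, so the realised period
  mean matches the condition exactly while the year-to-year structure stays
  random. Country shares are a fixed Dirichlet draw; each country-year
  total is split across events by a uniform Dirichlet.
* **Historical block**: 117 port-level period records of which exactly 6
  report both cost and quantity, 57 cost only, and 54 neither; true
  per-port masses are 10^N(7.2, 0.69) log₁₀-kg and costs follow a true rate
  of 4×10⁻⁴ currency/kg with lognormal scatter (σ = 0.15 on the log scale),
  so cost-derived masses are noisy in a controlled way.

**What passing tests do and do not show.** The suite demonstrates that the
estimation machinery is correct (unit conversions, filters, conservation,
convergence, coverage of known truth) and that, under pools and removal
magnitudes matching the stated study conditions, the pipeline reproduces the
implied headline carbon numbers. It does not validate the realism of those
conditions themselves: real %TOC fields are spatially autocorrelated, real
records have reporting biases (e.g. landed cargo understating screened
sediment), and real coastlines are not straight. Results on real data
inherit those caveats.

## Numerical and degenerate-input choices

* Sample SDs use the n−1 denominator throughout.
* Constant log-mass samples give σ = 0 and an undefined Shapiro–Wilk; the
  model is returned flagged degenerate rather than erroring at fit time, and
  sampling from an n < 3 model is refused.
* A single-value %TOC pool is legal and collapses the simulation to a
  deterministic product — used widely in tests as the zero-noise limit.
* Exclusion filters never error on empty input; empty *output* pools do
  error, naming the pool, because a downstream simulation cannot draw from
  nothing.
* Equality comparisons on run totals in tests are bit-exact by design:
  determinism is a contract, not a tolerance.

## Known limitations

* No spatial autocorrelation model for %TOC; draws are i.i.d. from pools.
* No screening/overflow correction for aggregate records (landed mass is a
  lower bound on disturbed mass).
* Single sediment density for all volume conversions.
* No currency deflation in the cost-rate calibration.
* Dredge-spoil disposal, remineralisation and CO₂ flux are out of scope.
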