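# Methods

## Scope

`pmhia` implements a long-term health-impact assessment (HIA) for ambient
PM2.5 together with a seasonal linear model of daily concentrations, for
seven Iranian cities (Arak, Esfahan, Ahvaz, Tabriz, Shiraz, Karaj, Mashhad,
study window 2019–2020). The raw hourly monitoring feeds behind the
published study were never deposited, so a synthetic generator with known
ground truth stands in for them; the published per-city baseline
incidences, relative risks, exposure summaries and impact tables are bundled
in `pmhia.reference` as machine-readable inputs that anchor the arithmetic.

## Exposure processing

Hourly pollutant records with value ≤ 0 are removed at ingest and counted
(zero and negative concentrations are instrument sentinels); meteorology
keeps non-positive values, since winter temperatures in these cities are
legitimately negative. Duplicate timestamps are an error, not averaged —
silent averaging would mask feed faults. A calendar day enters the daily
series when at least `min_completeness × 24` hourly values survive; the
default 0.75 (18 of 24 hours) is the conventional air-quality validity
rule. Annual summaries report the sample SD (n − 1 denominator). The
binned exposure distribution uses left-closed bins aligned to multiples of
the bin width (default 1 µg/m³) spanning the observed range; midpoints are
the category concentrations and day fractions the category weights. By
construction the midpoint-weighted mean is within half a bin width of the
true mean, so AP in binned mode converges to annual-mean mode as the width
shrinks.

## Concentration–response functions

Three forms:

* **log-linear** — `RR(c) = exp(ln(rr)/Δ · max(0, c − c0))` for a
  published `rr` per `Δ` µg/m³ (default 10). One increment above the
  cutoff reproduces the published RR and `RR(c0 + kΔ) = rr^k`. The
  bundled all-cause curve is RR 1.062 (95% CI 1.04–1.083) per 10 µg/m³.
* **IER** — `RR(z) = 1 + α(1 − exp(−γ(z − z_cf)^δ))` above the
  counterfactual `z_cf`, bounded by 1 + α; used for cause-specific
  mortality (IHD, stroke, COPD, lung cancer, ALRI). No parameter values
  were published, so parameters are user-supplied; the fixture set in
  `pmhia.synthetic.fixture_crfs` is synthetic and exists only so the
  pipeline runs end to end.
* **implied-AP** — `RR = 1/(1 − AP)`, the single-category inversion of a
  published attributable proportion; used to reproduce published impact
  tables whose underlying CRF configuration is not recoverable.

The cutoff default is 10 µg/m³, the WHO annual PM2.5 guideline, and is
configurable: back-computation shows the published all-cause APs are not
reproducible from the published annual means under any fixed cutoff with
the log-linear curve alone (e.g. Arak: AP 8.15% from the 24.12 µg/m³ mean
with c0 = 10, versus 7.39% published), implying the original software used
a binned daily distribution and/or a different internal counterfactual.
AP reproduction from annual means is therefore *not* asserted anywhere;
the published APs are treated as inputs when reproducing the rate chain.

## Impact equations

With exposure categories c and proportions P(c),

    AP = Σ_c (RR(c) − 1)·P(c) / Σ_c RR(c)·P(c)
    IE = I × AP                    (I = baseline incidence per 100,000/yr)
    NE = IE × N / 100,000          (N = at-risk population)

The explicit /100,000 in NE makes the per-100,000 scale of IE concrete;
literal multiplication would give absurd counts. Age groups are
endpoint-specific (≥30 all-cause/COPD/LC, ≥25 IHD/stroke, ≤5 ALRI). The
low/central/high RR bounds propagate through the whole chain, and since
`AP = 1 − 1/Σ RR·P`, pointwise-ordered RR curves yield ordered AP, IE and
NE. All arithmetic is kept at full precision; rounding (AP as percent to
2 decimals, IE to 2 decimals, NE to integers) happens only when a report
table is emitted.

Published excess-case counts are checked only as an internal round trip
(N implied by NE/IE feeds back to NE), because the study's at-risk
population counts were not published; the fixture populations shipped with
the package are synthetic round numbers of realistic magnitude.

## Seasonal linear model

Daily PM2.5 is regressed on an intercept, 0/1 indicators for each calendar
month present except a reference month, a 0-based day-index trend, and
daily-mean meteorological covariates (temperature, relative humidity, wind
direction, wind speed, pressure), by OLS with SEs from σ̂²(XᵀX)⁻¹,
σ̂² = RSS/(n − p), and two-sided t p-values — a plain linear model, no
autocorrelation correction or multiple-testing adjustment, matching how
such tables are conventionally reported. The reference month defaults to
the first month appearing in the series. Rows with any missing covariate
are dropped listwise and counted. Rank deficiency raises an error naming
the dependent columns (pivoted QR). Fitting is daily-resolution on the
24-h means. The fit itself is delegated to `statsmodels.OLS`; tests check
it against a hand-rolled normal-equations solution. A constant response
is legal and reported with R² = 0.

## Synthetic generator

`simulate_hourly` draws exactly the model above: covariates follow
seasonal cosines (mean, amplitude, peak day-of-year, Gaussian noise,
optional clipping) calibrated so annual summaries land in the range
published for these cities; the daily PM2.5 mean is the linear predictor
plus i.i.d. N(0, σ²) noise (defaults: intercept 12 µg/m³, trend
0.005 µg/m³/day, summer month effects up to +6 µg/m³, σ = 5 µg/m³, one
365-day year). Hourly values add within-day noise that is *centred per
day*, so a complete day's 24-h mean equals the model value exactly — with
σ = 0, no missing hours and no sentinels, OLS recovers every coefficient
to machine precision, which pins the whole aggregation + regression chain.
Hours are then deleted independently (default 5%) and a small fraction of
retained pollutant hours (default 1%) is replaced by zero/negative
sentinels to exercise cleaning; the truth record counts both.

What the defaults do **not** emulate: autocorrelated residuals (an AR
option is deliberately absent from the defaults; the plain-OLS SEs are
exact under the default model), dust-storm extremes, spatial station
structure, or instrument drift. Note one deliberate realism effect: with
missing hours and sentinel removal, the observed daily means and daily
covariate means deviate slightly from the generating values, an
errors-in-variables perturbation under which nominal 95% CI coverage can
drop noticeably for some replicates (visible in `analysis/04`). The
coverage acceptance check therefore runs the generator with missingness
and sentinels off, where coverage is exactly nominal; passing it shows the
estimator and its intervals are correct under the model's own assumptions,
not that real monitoring gaps are harmless.

## Problem sizes and numerical choices

Simulation-based checks use one synthetic year (365 days, ~8,700 hourly
records per variable) and 50 replicates for interval coverage, 25 for the
bias check — sizes at which the Monte-Carlo error of the checked
quantities is well below the asserted tolerances. Oracle equalities are
asserted at 1e-12 (sums, means, AP evaluator) or 1e-8 relative (OLS vs
normal equations). Coverage is asserted within ±0.035 of 0.95, a
binomial-scale band inflated for the correlation of coverage events within
a replicate (all terms share σ̂). Bin proportions must sum to 1 within
1e-12. Ties at bin edges follow the left-closed convention; a value on
the top edge opens a new bin.

## Known limitations

* Published Table-4-style regression coefficients are not reproducible —
  they require the unreleased hourly data; the package reproduces the
  *procedure* and its formatting, validated by parameter recovery.
* Cause-specific (IER) impact numbers from the fixture parameters are
  illustrative only.
* Single-station, single-pollutant; no spatial averaging rule is provided
  because none was published.
* Wind-direction summaries in the published data (max ≈ 55°) suggest an
  undocumented prior transform, and the "pressure" field's published range
  (0–335) is not plausible in millibars; both are treated as opaque
  numeric covariates.
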