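# Methods

## Model and procedure

The package implements the standard Gaussian model of internal quality
control: control observations of one material lot on one chart are treated
as i.i.d. normal with lot mean μ and lot SD σ (CV = 100·σ/μ %). A chart is
monitored by standardising each observation against control limits
(center m, applied SD s) and evaluating the six classic Westgard rules on
the z-series. Rules are evaluated on a single ordered series per chart;
across-level and across-material rule variants are not implemented because
the pipeline treats each (analyte, control level) chart independently.

At lot changeover two limit schemes are compared on the incoming lot's
series:

1. **Cross-over CV** (`scheme="crossover_cv"`): the outgoing and incoming
   lots' CVs are pooled and applied around a target mean. The pooled CV is
   the degrees-of-freedom-weighted root mean square of the two CVs. This
   form was chosen because, when the two lot means are equal, it is
   algebraically identical to the CV of the classical pooled within-lot
   variance (verified numerically in the test suite); an unweighted
   arithmetic mean of the two CVs is available
   (`crossover.method = arithmetic_mean`) for sensitivity analysis. The
   target mean is configurable: the incoming lot's provisional mean
   (default), the outgoing lot's historical mean, or an explicit value —
   practice varies and no single pairing is canonical, so all three are
   supported.
2. **Actual** (`scheme="actual"`): the incoming lot's own established mean
   and sample SD (n−1 denominator).

### Failure classification

1_2s is a *warning*; all other rules are *rejections*, matching the
conventional use of 1_2s as a screening rule. Hits are reported at every
index where a rule's window completes; windows are **not** reset after a
rejection. The counting policy (`exclusive_by_point`) then collapses all
hits at one index into a single failure — a rejection if any rejection
rule completed there, otherwise a warning. This guarantees the additivity
total = warning + rejection at chart level and for column totals, which
the reference table satisfies row by row.

Comparisons at limit lines are **strict**: z exactly equal to 2.0 (or 3.0,
1.0, 0.0) does not fire the corresponding rule. Some implementations use
≥; strictness was chosen for determinism on data that lands exactly on a
line (e.g. coarsely rounded control results) and is applied uniformly.

### Why wider limits suppress rejections

Replacing the applied SD s by λ·s with λ ≥ 1 divides every z by λ, so the
hit set of each threshold rule (1_2s, 1_3s, 2_2s, R_4s, 4_1s) can only
shrink, while 10_x (a sign rule) is unchanged provided the center is
fixed. This monotonicity — property-tested in the suite — is the mechanism
by which an overstated transitional SD under-reports rejection failures.

## Comparison pipeline

For each chart carrying both lots, `run_comparison`:

1. summarises the outgoing lot and the incoming lot's *establishment
   window* — its first `establishment_runs` observations (default 20,
   mirroring the convention of establishing limits over ~20 runs);
2. derives cross-over limits (pooled CV × target mean, optionally
   multiplied by `crossover_inflation` λ) and actual limits (establishment
   window mean/SD);
3. evaluates the rules over the **whole** incoming-lot series under both
   limit sets and tallies failures.

Establishing the actual limits from the establishment window, rather than
the full series, reflects how laboratories actually fix targets before
monitoring continues; it also means that error events injected after the
window do not contaminate the estimate. `crossover_inflation` models how
far a pooled transitional SD can overstate the incoming lot's true
imprecision without requiring the simulator to produce a badly mismatched
outgoing lot.

A chart "differs" between conditions when **any** of (total, warning,
rejection) differ. The published per-chart Yes/No labels are internally
inconsistent with any single criterion we could identify (group 17's
composition changes from 2 warnings to 2 rejections yet is labelled "No",
while analogous groups 3 and 16 are "Yes"), so the computed flag is
reported alongside the retained published label rather than forced to
agree; on the reference table the any-component criterion flags 12 charts
against 11 published "Yes" labels, the sole disagreement being group 17.

### Significance tests

- 2×2 test on the warning/rejection composition of the column totals:
  chi-square with Yates continuity correction when all expected counts are
  ≥ 5, otherwise a two-sided Fisher exact test (the conventional
  "when appropriate" switch); the sample odds ratio is reported alongside.
- Two-sided paired t-test on per-chart total failures — paired because the
  same 18 charts are measured under both conditions.
- α = 0.05 throughout, no multiple-testing correction (a single
  pre-specified threshold is applied, matching the study design).
- Degenerate inputs (a zero margin; paired differences all zero) return
  p = 1 with a degeneracy flag instead of raising.

## Synthetic data

The simulator generates x_i = μ + σ·(ε_i + Δ·1[i ≥ t₀] + δ·i) per lot,
with ε_i standard normal, optional step shift Δ (in true-SD units) from
within-lot run t₀, optional drift δ per run, and scale-contaminated
outliers (each point's noise SD inflated by `outlier_scale` with
probability `outlier_prob`). An optional `decimals` parameter rounds
reported values to emulate instruments with coarse result reporting (off
by default). One master seed drives independent per-(chart, lot) RNG
child streams, so studies are bitwise reproducible and charts pairwise
distinct.

The `paperlike` preset emulates the study design — 18 two-lot charts, 20
runs of the outgoing lot, 30 of the incoming — with analyte means spread
log-uniformly over 10–500 units and CVs of 2–5 %, values typical of
routine clinical-chemistry controls; the outgoing lot is offset by up to
±2 % in mean and up to 1.4× noisier, as an aged lot plausibly is. Eleven
of the 18 charts carry a 2.5-SD shift over the last 10 incoming-lot runs
(after the 20-run establishment window), mirroring the 11-vs-7
different/comparable split. These settings are illustrative of the study's
*structure*; no distributional parameters for the original analytes were
published, so nothing here claims to reproduce the original measurements.
What passing simulation-based tests show is that the pipeline's mechanics
(estimation, rule evaluation, counting, direction of the scheme contrast)
are correct under the stated Gaussian model — not that real instrument
data, with autocorrelation, calibration cycles, or non-Gaussian tails,
would yield the published per-chart counts. Those counts are shipped as a
packaged fixture and only aggregated, never re-derived.

## Numerical and design choices

- Sample SD uses the n−1 denominator everywhere; n < 20 for limit
  establishment is a warning diagnostic (`QCWarning`), not an error;
  n < 2 is an error.
- Zero-width limits (SD = 0, e.g. from constant series) raise
  `DegenerateLimitsError` rather than producing infinite z.
- CSV interchange is comma-separated UTF-8 with a header; floats are
  re-read with round-trip precision so write∘read is the identity.
- `run_index` is an abstract ordering, not a timestamp; "20 days" style
  conventions are expressed in runs because runs-per-day varies.
- Monte-Carlo problem sizes (10,000 in-control points for false-alarm
  rates; 200 replicates for the directional contrast; 100 seeds × 10,000
  for CV recovery) were chosen so binomial/normal-theory standard errors
  are small relative to the tested margins.

## Known limitations

- Single-level rule evaluation only; no across-run or across-material
  2of3₂ₛ/R₄ₛ variants.
- R_4s is operationalised as consecutive opposite ±2 SD excursions
  (range > 4 SD across adjacent points); within-run replicate structure is
  not modelled.
- The simulator does not model instrument autocorrelation, calibration
  cycles, or reagent-lot drift within a control lot.
- Sigma-metric-based rule selection and patient-based real-time QC are out
  of scope.
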