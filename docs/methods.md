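# Methods

This note documents the modelling and numerical choices behind
`wearcohort`: what the pipeline computes, what the synthetic cohorts do and
do not emulate, and where the design was genuinely open.

## Harmonization model

A dataset is a set of participant-days. Each record belongs to one
provider, and only the variables that provider's cloud API exposes are ever
present; everything else is absent, never zero-filled. A recorded zero
(e.g. 0 steps on a worn-but-idle day) is a datum; a missing cell is not.
The capability matrix is hard-coded from the providers' published daily
endpoints but can diverge from reality as APIs evolve, so values outside a
provider's set are dropped with a warning at ingest rather than treated as
corruption.

Three providers need fields beyond their analysis variables to evaluate
their wear rule (Garmin: sleep/sedentary/LPA; Samsung:
sedentary/LPA/MPA/VPA; Polar: nonwear). These are accepted in exports and
kept as *rule-only* fields: they feed the valid-day decision but never an
analysis mean. This resolves the apparent inconsistency of a provider whose
wear rule references variables missing from its own variable list.

Dates are time-zone-free calendar dates; a provider-day is taken as
reported. The collection window is fixed at 2019-01-01..2020-12-31 and
enforced at ingest.

## Valid days

The underlying concept is a single one — at least 10 h of wear — but each
provider only supports one proxy for it:

| rule | providers | default threshold | valid iff |
|---|---|---|---|
| step floor | Apple, Fitbit, Google Fit, Oura, Withings | 150 steps | steps > 150 |
| wear sum | Garmin, Samsung | 600 min | sleep+sedentary+LPA+MPA+VPA > 600 |
| nonwear cap | Polar | 840 min | nonwear < 840 |

All inequalities are strict. The step-floor boundary is genuinely
ambiguous between "more than 150" and "fewer than 150 excluded" (150
valid); the strict reading is the default and `step_floor_inclusive`
switches to the other. The same ambiguity exists for "at least 10 hours"
vs "> 10 hours"; strict ">" is used. All thresholds are configurable
because the proxies themselves are conventions, not physical constants.

A day whose rule inputs are missing cannot demonstrate wear and is invalid
with a reason code ("insufficient wear evidence" for an incomplete wear
sum) rather than an exception: in pooled multi-provider data, partial
records are ordinary, not exceptional. Every excluded day lands in a
reason-coded exclusion log, so input rows partition exactly into
analysis-eligible and logged-excluded.

MVPA = MPA + VPA, derived only when both components exist. Consequently
the number of contributing days may differ between steps and MVPA for the
same participant-period; each variable's mean uses its own day count.

## Aggregation

Per-participant period means are plain arithmetic means over the valid
days in the period that carry the variable. `min_days` (default 1)
suppresses summaries with fewer contributing days; the default is
deliberately permissive because the analysis design gives no per-month
minimum, but epidemiological practice often uses 4–10 days, so it is
config-exposed. Yearly (March–December) means are computed over *days*,
not as means of monthly means; this makes the valid-day-weighted
recombination identity exact: for the split month,
n₁m̄₁ + n₂m̄₂ = (n₁+n₂)·m̄_whole to machine precision, which the test
suite asserts at ≤1e-9 relative error.

## Paired comparisons

Pairs are formed by intersecting the participants of the two periods;
differences are later minus earlier (so a lockdown drop is negative).
Normality of the differences was originally a visual histogram judgement;
the reproducible proxy here is Shapiro–Wilk at α=.05 on the paired
differences. Because such data essentially always resolve to *t* for
steps/AEE and Wilcoxon for MVPA (MVPA medians of integer minutes are
heavily tied and skewed), that assignment ships as the default per-variable
override, with the Shapiro decision used when an override is unset.

Wilcoxon conventions: zeros dropped before ranking (Pratt's method
available by flag), ties mid-ranked, exact null distribution when the
effective n ≤ 25 with untied magnitudes, tie-corrected normal approximation
otherwise. The reported location is the median of the raw differences with
their IQR — not the Hodges–Lehmann pseudomedian — matching the
"median (IQR)" reporting convention; with n paired differences the IQR
bounds are linear-interpolated quartiles. The exact p is verified in the
tests against brute-force enumeration of all 2ⁿ sign assignments for every
sign pattern at n = 3..12.

The t interval is the equal-tailed 95% t interval. Degenerate inputs
(zero-variance differences, all-zero differences) yield flagged results
with undefined p rather than exceptions. No multiplicity correction is
applied by default across the 39 report cells (13 contrasts × 3
variables), consistent with how such surveillance tables are reported; a
Holm option exists.

## Synthetic cohorts

The generator emulates the *structure* the pipeline assumes, at the study's
scale: 113 participants split 39 Fitbit / 74 Garmin, one record per
participant-day over 2019–2020 minus ~3% missing days.

Per participant *i* and day *t*:

- baseline `b_i ~ lognormal(median 8000, GSD 1.4)` steps;
- seasonal factor `s(t) = 1 + 0.15·cos(2π(t − t_Jul1)/365.25)` — a single
  annual harmonic peaking July 1, the minimal structure that makes
  month-matched comparison meaningful;
- `steps_it = round(max(0, b_i·s(t) + N(0, 2500)))`;
- `AEE_it = max(0, 0.04·steps_it + N(0, 40))` kcal;
  `TEE_it = REE_i + AEE_it` with `REE_i ~ N(1550, 150)` kcal (floored at
  1100);
- `MVPA_it = round(max(0, N(35, 20)))` min, split 70/30 into MPA/VPA;
- wear components on worn days: sleep ~ N(430, 50) clipped to [180, 720],
  LPA ~ N(210, 60) clipped to [0, 600], sedentary chosen to pull the
  five-component sum toward a U(550, 1000) min target;
- nonwear days (probability 0.05): steps ~ U{0..149}, wear-component sum
  ~ U(100, 500) min, nonwear ~ U(900, 1440) min — constructed so the
  step-floor, wear-sum and nonwear-cap families all exclude them, mirroring
  the use of a step floor as a wear-time proxy;
- days are dropped independently with probability 0.03;
- the lockdown effect is an additive shift (default −800 steps/day,
  −75 kcal/day AEE, applied to TEE as well) over Mar 13–31 2020, floored
  at zero.

Records are then restricted to each provider's capability ∪ rule-only
fields. Everything is drawn from one seeded generator; identical
config + seed gives byte-identical output.

The effect sizes sit near the magnitudes reported for the Norwegian
lockdown in consumer-tracker data; the variance components are plausible
choices, since no real variance components are published for such a
cohort. What the generator does **not** emulate: within-week structure,
autocorrelated behaviour, participant-level seasonal phase differences,
device-model measurement bias, drop-out, or any sleep architecture. Tests
passing on these cohorts therefore demonstrate the pipeline's correctness
and calibration under the stated generative model, not tracker accuracy or
population representativeness.

## Seasonal confounding in the split-March contrasts

Month-matched contrasts (April vs April, …) compare identical calendar
windows across years, so the seasonal term cancels exactly in paired
differences. The three split-March contrasts do not: whole March 2019 vs
Mar 1–12 2020 (or Mar 13–31 2020) compares windows with different seasonal
means. Under this generator's conditions the residue is material — about
−180 steps/day for the pre-lockdown window, +140 for the post-lockdown
window, and +320 for the within-March contrast — visible in the worked
example's "March 1-12" row, which is significantly negative with no
injected effect in that window. This is a faithful property of the study
design itself, not an artifact: any comparison of unequal calendar windows
carries the within-month trend.

The calibration and recovery checks in the acceptance tests therefore use
season-matched windows, where the design is unconfounded: type-I error is
measured on March 2019 vs whole March 2020 (rejection at α=.05 stays
within [0.02, 0.09] over 200 null cohorts for both tests), and recovery of
the injected effect on Mar 13–31 2019 vs Mar 13–31 2020 (mean estimate
within ±100 steps of −800 and ±15 kcal of −75 over 50 cohorts, correct
sign always). The confounded paper-style contrast is additionally checked
qualitatively: negative and significant under injection.

## Problem sizes and determinism

The shipped simulations use the full cohort scale (113 × 731 days,
~80k records per cohort); the Monte Carlo checks use 200 cohorts for
type-I calibration, 50 for recovery, and the acceptance script 100 and 25
respectively — sizes at which the binomial uncertainty of a rejection rate
(~±1.5–4 points) is small relative to the asserted bands. All randomness
flows from `numpy.random.default_rng(seed)`; the CLI's `--seed` overrides
the config seed for both simulation and analysis, and repeated runs are
byte-identical.

## Known limitations

- The canonical CSV schema and provider dialect mappings are this
  package's own conventions; no provider's real export format ships here.
- Wilcoxon IQR bounds use linear-interpolated quartiles; reports produced
  with other quantile conventions will differ in the dispersion column.
- `assess_normality` is a proxy: at n ≈ 100 Shapiro–Wilk has its own
  error rates (~5% of truly normal difference vectors are sent to
  Wilcoxon), which is why the per-variable override is the shipped default.
- No imputation, covariate adjustment, stratification, or epoch-level
  wear algorithms: the pipeline consumes daily summaries only.
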