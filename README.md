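# wearcohort

Harmonization and paired longitudinal analysis of daily activity summaries
from consumer activity trackers (Apple, Fitbit, Garmin, Google Fit, Oura,
Polar, Samsung, Withings).

Consumer trackers are an attractive data source for physical-activity
surveillance in epidemiology: people wear them continuously for years, so a
single data pull yields long retrospective daily series. The catch is
heterogeneity — each provider's cloud exposes a different subset of daily
variables, and wear time (without which a daily summary is meaningless) must
be inferred from different proxies per provider. `wearcohort` implements the
full desk-side workflow for such a cohort:

1. **Ingest** provider exports into one canonical long CSV (one
   participant-day per row), enforcing each provider's capability set,
   the 2019–2020 collection window, and missing-≠-zero semantics; an
   `anonymize` step replaces identifiers and destroys the identifier map.
2. **Valid-day filtering** per provider: steps > 150 (Apple, Fitbit,
   Google Fit, Oura, Withings), sleep + sedentary + LPA + MPA + VPA > 10 h
   (Garmin, Samsung), or nonwear < 14 h (Polar); MVPA is derived as
   MPA + VPA where both exist.
3. **Aggregation** of valid days into per-participant period means
   (steps/day, AEE kcal/day, MVPA min/day) over calendar months, the
   March 2020 lockdown split (Mar 1–12 vs Mar 13–31, the Norwegian
   lockdown date being March 12), and March–December yearly spans.
4. **Paired comparison** of each 2020 period against its 2019 counterpart
   (plus pre- vs post-lockdown within March 2020), restricted to
   participants observed in both periods. For paired differences
   d₁,…,dₙ the package reports either the paired *t* test
   (d̄ with 95% CI d̄ ± t₀.₉₇₅,ₙ₋₁·s/√n) or the two-sided Wilcoxon
   signed-rank test (median of differences with IQR; exact null
   distribution for effective n ≤ 25, tie-corrected normal approximation
   above), chosen per variable by a Shapiro–Wilk check or a shipped
   override (t for steps/AEE, Wilcoxon for MVPA). Two-sided p < .05 is
   flagged significant.
5. **Synthetic cohorts**: because real cohorts of this kind are anonymous
   and undepositable, a fully seeded generator simulates the study
   conditions — 113 participants (39 Fitbit, 74 Garmin), daily records for
   2019–2020 with seasonal variation, nonwear and missing days, and an
   injectable lockdown effect (−800 steps/day, −75 kcal/day over
   Mar 13–31 2020).

## Worked example

```sh
wearcohort simulate --seed 1 --out cohort.csv
wearcohort analyze --in cohort.csv --outdir out
wearcohort report --outdir out --format md
```

The first command writes 80,164 daily records (113 participants; ~3% of
days missing). `analyze` filters them to 75,061 valid person-days, builds
the period summaries and writes the comparison table plus monthly plot-data
series. The rendered report begins:

| comparison | steps (steps/day) | steps p | aee (kcal/day) | aee p | mvpa (min/day) | mvpa p |
|---|---|---|---|---|---|---|
| March-December | -71 (-109 to -32) | 0.00041 | -6 (-7 to -4) | 4e-09 | -0 (-1 to 1) | 0.77 |
| March 1-12 | -298 (-477 to -119) | 0.0013 | -12 (-20 to -5) | 0.0017 | 3 (-3 to 5) | 0.027 |
| March 13-31 | -779 (-923 to -635) | 6.3e-19 | -73 (-79 to -67) | 2.2e-45 | -0 (-4 to 3) | 0.73 |
| April | 29 (-86 to 143) | 0.62 | 1 (-3 to 6) | 0.61 | -1 (-5 to 4) | 0.053 |

Each cell is the paired estimate (later period minus earlier period) with
its 95% CI or IQR. The "March 13-31" row compares March 2019 with the
post-lockdown window of March 2020 and recovers the injected effect: a
mean reduction of 779 steps/day and 73 kcal/day of activity energy
expenditure, both strongly significant, while the month-matched contrasts
from April onward are null — the simulated lockdown dip is temporary, and
the paired month-to-month design controls the seasonal cycle. The
"March 1-12" row illustrates a design caveat discussed in
`docs/methods.md`: comparing whole March 2019 against part of March 2020
leaves a seasonal-trend residue in the estimate even with no effect in
that window.

All of this is equally usable as a library:

```python
from wearcohort import CohortConfig, analyze_dataset, generate

outputs = analyze_dataset(generate(CohortConfig(seed=1)))
print(outputs.report.head())
```

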