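# faerspv

Pharmacovigilance signal mining for FAERS-style spontaneous adverse-event
reports, built for epidemiologists and drug-safety researchers who analyze
the FDA Adverse Event Reporting System's quarterly ASCII releases (or any
database with the same DEMO/DRUG/REAC/THER structure). The package covers
the full desk workflow of a post-marketing surveillance study: ingestion
and deduplication, primary-suspect cohort construction, reporting-odds-ratio
disproportionality at MedDRA PT and SOC level, time-to-onset
characterization, reporter-type subgroup comparison — and a synthetic-data
generator with planted ground truth, so every stage is testable without
downloading a multi-gigabyte database or licensing MedDRA.

## The statistics at the core

**Deduplication.** FAERS cases accumulate versions under one CASEID. One
version per case is kept: the one with the latest FDA receipt date
(FDA_DT), breaking ties by the largest PRIMARYID.

**Reporting odds ratio.** For a drug–event pair, counting (report, term)
pairs with within-report terms deduplicated,

```
            a·d                                          _______________
ROR  =     -----,    95% CI = exp( ln ROR ± 1.96·√ 1/a + 1/b + 1/c + 1/d )
            b·c
```

where *a* = target-drug reports with the term, *b* = target-drug pairs with
other terms, *c*, *d* likewise for the comparator (the rest of the
database). A term is a **significant signal** when ROR₀₂₅ > 1 and N ≥ 2; a
significant signal absent from the drug's label is an **unexpected signal**.
Zero cells are flagged incalculable — no continuity correction, no
multiple-testing adjustment (deliberately, matching the ROR screening
tradition; see `docs/methods.md`).

**Weibull shape-parameter (WSP) test.** Onset intervals (event date −
therapy start, day-precision dates only, non-negative) are fitted with a
two-parameter Weibull(β, α) by maximum likelihood; the Wald 95% CI for the
shape β classifies the hazard: CI < 1 → *early failure* (risk declines with
time on drug), CI ∋ 1 → *random failure*, CI > 1 → *wear-out failure*
(risk grows). Kaplan–Meier cumulative incidence (via lifelines; no
censoring, so it equals the empirical CDF) summarizes how quickly events
accrue.

## Worked example

`examples/04_time_to_onset.py` simulates a three-drug surveillance window
(cohorts of 2158/258/1043 reports with Weibull onset models planted at
β = 0.81/1.48/0.81), runs the full pipeline — ingest, deduplicate, select
each primary-suspect cohort, compute onset intervals, fit the WSP test,
estimate KM incidence — and prints:

```
patisiran: 676 usable onset records (of 2158 cohort reports)
  median onset 193 days (IQR 61-475.2)
  Weibull beta 0.82 (95% CI 0.77-0.87), true 0.81 -> early_failure
  cumulative incidence: 14.3% by day 30, 48.4% by day 180

vutrisiran: 88 usable onset records (of 258 cohort reports)
  median onset 112 days (IQR 70-167.2)
  Weibull beta 1.59 (95% CI 1.34-1.88), true 1.48 -> wear_out_failure
  cumulative incidence: 12.5% by day 30, 80.7% by day 180

inotersen: 358 usable onset records (of 1043 cohort reports)
  median onset 200 days (IQR 62-598.5)
  Weibull beta 0.77 (95% CI 0.71-0.83), true 0.81 -> early_failure
  cumulative incidence: 14.5% by day 30, 48.0% by day 180
```

Reading it: only reports with full day-precision dates on both ends
contribute (hence 676 of 2158); the fitted shapes recover the planted
values, and the CI-based classification separates the early-failure drugs
(risk concentrated soon after start) from the wear-out drug whose risk
rises with treatment time. The other examples walk through simulation
(`01`), descriptive tables (`02`), ROR screening with expectedness and
cross-drug overlap (`03`), and reporter subgroups (`05`).

A thin CLI exists for the one shell-worthy task:

```bash
faerspv simulate --out quarter_dir --seed 7          # synthetic quarter + truth.json
```

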