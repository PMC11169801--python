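# Methods

This note records the statistical model, the conventions the pipeline
commits to where the field leaves room, and what the synthetic-data
generator does and does not emulate.

## Data model and ingestion

A quarter is four delimited tables — DEMO (one row per report version:
identifiers, receipt date, demographics, reporter occupation, event date),
DRUG (drug names with role codes PS/SS/C/I), REAC (MedDRA preferred
terms), THER (therapy start dates) — joined on PRIMARYID. The dialect
(delimiter `$`, one header line, no quoting, declared column sets) is a
data object, so tests and other sources can use different delimiters.
Readers are conservative: rows in = rows kept + rejects, each reject with
a machine-readable reason; child rows whose PRIMARYID lacks a DEMO row are
kept but flagged. Dates are parsed to a `PartialDate` with precision
day/month/year/missing/invalid rather than coerced — the time-to-onset
stage needs to distinguish an unknown day from a missing date. FDA_DT and
PRIMARYID are treated as orderable integers.

Event dates are taken from the DEMO record and therapy starts from THER;
when a report carries several therapy rows, the earliest day-precision
start is used. Reports with no reaction rows are skipped at assembly with
a logged count. One report yields at most one onset record.

## Deduplication

One version per CASEID: latest FDA_DT, ties broken by largest PRIMARYID —
always the most recent version of the case. The operation is idempotent
and order-independent; output is sorted by caseid. An exact tie on both
keys cannot occur in real data (PRIMARYID is unique); if synthetic input
produces one, the first-seen row is kept and a warning logged.

## Cohorts and descriptive summary

Drug matching is word-boundary containment of normalized synonyms
(trimmed, case-folded, whitespace-collapsed), because verbatim names carry
salt/dose/formulation suffixes. A cohort is the deduplicated reports
carrying the target drug in the primary-suspect (PS) role; its size is the
count of unique caseids. The descriptive table breaks the cohort down by
sex, age band, reporter type, and receipt year, each with an explicit
missing category; percentages use the full cohort (missing included) as
denominator and are rounded half-up to one decimal. Age bands are <18,
18–65, >65 with both boundary ages in the middle (closed) band — a stated
convention, since published tables rarely say. Ages are converted from
unit codes (DEC×10, YR, MON/12, WK/52.18, DY/365.25, HR/8766); results
outside [0, 150] years are treated as missing with a warning. Reporter
classes partition occupation codes: {MD, PH, OT, HP} medical, {CN, LW}
non-medical, else unknown; both sets are parameters.

## Disproportionality

The counting unit is the (report, term) pair with terms deduplicated
within a report; at SOC level a report contributes once per SOC however
many of its PTs map there. The comparator is the deduplicated database
window minus the cohort (configurable to include it). ROR is the Wald
odds ratio (a·d)/(b·c) with CI exp(ln ROR ± 1.96·√Σ1/cell); any zero cell
flags the estimate incalculable rather than applying a Haldane–Anscombe
correction — the N ≥ 2 signal threshold already excludes the cases a
correction would rescue, and uncorrected RORs are what screening studies
print. Signal rule: ROR₀₂₅ > 1 and N ≥ 2, applied identically at PT and
SOC level. Rankings are by N descending with alphabetical tie-break for
reproducibility. Exclusion lists (outcome terms, injection/infusion
terms, disease-symptom terms) and drug-label term lists are plain text
inputs, one term per line with `#` comments — they are study-specific
editorial choices, not code. No multiple-testing adjustment is applied;
with 50 terms per drug screened, a handful of borderline signals per
screen are expected false positives. This is a deliberate limitation,
consistent with ROR screening practice, and users needing error control
should apply FDR on the result table.

PT→SOC mapping is a user-supplied two-column table; MedDRA is licensed
and no dictionary content ships with the package. Unmapped PTs route to
an `UNMAPPED` sentinel SOC and are logged once each.

## Time to onset

Records require day precision on both dates and event ≥ start; exclusions
are tallied by reason (missing, imprecise, invalid, negative). Quartiles
use linear interpolation. The Weibull fit solves the profile score
equation for β by bracketed root finding (the profile score is strictly
decreasing), recovers α = (mean tᵢ^β)^{1/β} in closed form, and requires
the score below 1e-8 at the solution; the 95% CI for β is a Wald interval
on log β from the analytic observed-information matrix. Same-day onsets
(0 days) are set to 0.5 day before fitting, since the Weibull support is
positive and dropping them would bias β downward; the replacement value
and the n ≥ 10 sample floor are parameters. The Wald-on-log interval is
symmetric in log space and can differ from profile-likelihood intervals
at small n; the package's recovery tests quantify the consequence (shape
MLE bias < 5% at n = 500; ≈ +2–3% upward bias at n = 73). Kaplan–Meier
estimation is delegated to lifelines with all observations marked as
events: spontaneous reports are events by construction, so the KM
cumulative incidence equals the empirical CDF; the KM machinery is kept
so left-truncation or censoring variants can be added without API change.

## Reporter subgroups

Each stratum (medical / non-medical; unknown excluded from both) reruns
the same top-k screening. The comparator is restricted to the same
reporter class by default so each stratum's ROR is internally consistent;
`restrict_background=False` gives the whole-database comparator instead.
The comparison reports the intersection of the strata's significant term
sets and the two set differences, which are pairwise disjoint by
construction.

## Synthetic data generator

The generator emulates the joint structure the pipeline consumes, at desk
scale, with every planted parameter recorded in a truth manifest:

- **Vocabulary**: 200 invented two-word PTs with Zipf-like base
  frequencies, each prefix group mapping to an invented SOC (20 classes).
  Generated deterministically in code; no licensed dictionary content.
- **Signals**: a signal PT is carried by non-cohort reports with base
  probability q and by cohort reports with p = ROR·q/(1 − q + ROR·q), so
  the report-level odds ratio equals the target exactly. Because the
  pipeline's 2×2 uses pair margins, the measured disproportionality is
  ≈ p/q, slightly below the target for non-tiny q (7.48 vs 8 at
  q = 0.01) — the recovery tests use q = 0.01, where the gap is well
  inside CI width. Signals can be restricted to one reporter stratum.
- **Onsets**: per-drug Weibull(β, α) day intervals added to a uniform
  therapy start; receipt = event + 7–120 days, clipped to the window end
  (so the last window year accumulates a realistic pile-up of reports).
- **Duplicates**: at the duplicate rate, a case is cloned with a larger
  PRIMARYID and strictly later FDA_DT (a configurable fraction instead
  ties FDA_DT to exercise the PRIMARYID tie-break), so deduplication has
  a unique right answer recorded in the manifest.
- **Missingness**: per-field Bernoulli for sex/age/occupation; start and
  event dates degrade to month/year/missing by configurable mixes.
- Defaults mirror a three-drug TTR-inhibitor surveillance window
  2018–2023: cohorts 2158/258/1043; Weibull (0.81, 325), (1.48, 132),
  (0.81, 380) — scales chosen so the onset medians are 207/103/242 days
  via median = α·(ln 2)^{1/β}; ~55/45 medical/non-medical reporter mix;
  sex/age missingness 55%/65%; 15% duplicate rate; a 20,000-report
  background standing in for the full database at reduced scale.
- All randomness flows from one seed through a single generator with a
  fixed draw order; output files are byte-identical across runs.

What it does **not** emulate: real term frequencies and co-reporting
structure, drug co-medication patterns, reporting-rate trends over
calendar time, country/occupation correlations, and duplicate reports
whose field values *differ* between versions. Passing recovery tests
therefore demonstrates correctness of the pipeline's logic and estimators
under known truth, not robustness to every pathology of real spontaneous
data.

## Problem sizes in tests

The test suite runs the recovery studies at desk scale, chosen so each
study still has clear statistical resolution: 200 replicates for the
Weibull shape recoveries (n = 447 and n = 73, the published onset sample
sizes) and for planted-ROR coverage (quarters of 1,200 background + 250
cohort reports, q = 0.01, expected a ≈ 19); exhaustive ROR-vs-rational
arithmetic over all 2×2 tables with cells in 1..30; 200 exponential
samples of n = 500 for the failure-profile classification rate.

## Known limitations

- Wald intervals throughout (ROR and β); no exact or profile-likelihood
  options yet.
- No probabilistic record linkage beyond the CASEID rule; versions with
  conflicting field values are resolved purely by recency.
- No PRR/BCPNN/EBGM alternatives; ROR only.
- Month-precision onset dates are excluded rather than interval-censored.
- One onset record per report: multiple reactions on one report share the
  single event date FAERS provides.
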