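"""Reporting odds ratio (ROR) disproportionality analysis at PT and SOC level.

For a drug–event pair, the 2×2 contingency table counts (report, term)
pairs: *a* target-drug reports with the term, *b* target-drug report–term
pairs with other terms, *c* comparator reports with the term, *d*
comparator pairs with other terms. Then

    ROR = (a·d) / (b·c),
    95% CI = exp( ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d) )

and a term is a significant signal when the lower 95% bound exceeds 1 and
the term was reported at least twice (ROR_025 > 1 and N ≥ 2). Terms within
a report are deduplicated: a report contributes at most one pair per PT,
and at SOC level at most one pair per SOC regardless of how many of its
PTs map there.

No continuity correction is applied: a table with a zero cell is flagged
incalculable instead (the N ≥ 2 signal threshold makes a = 0 irrelevant,
and corrections change published RORs silently). No multiple-testing
adjustment is applied, a known limitation of the ROR screening tradition.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .model import CaseReport, normalize_term
from .preprocess import MeddraMap

__all__ = [
    "ContingencyTable",
    "RorEstimate",
    "SignalResult",
    "comparator_background",
    "build_contingency",
    "ror",
    "signal_criteria",
    "top_terms",
    "classify_expectedness",
    "cross_drug_overlap",
    "read_term_list",
    "signals_to_frame",
    "write_signal_table",
]

Level = Literal["PT", "SOC"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 counts behind one drug–term ROR (pair-counting units)."""

    a: int  # target drug, target term
    b: int  # target drug, other terms
    c: int  # comparator, target term
    d: int  # comparator, other terms
    term: str = ""
    level: Level = "PT"
    flagged_absent: bool = False  # term seen in neither cohort nor comparator

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        """Report count N for the term in the cohort (= a)."""
        return self.a


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float
    incalculable: bool = False


@dataclass(frozen=True)
class SignalResult:
    """One term's disproportionality result with the signal decision attached."""

    term: str
    level: Level
    n: int
    ror: float
    ci_low: float
    ci_high: float
    significant: bool
    expectedness: Literal["labeled", "unexpected", "not_significant"] = "not_significant"


def comparator_background(
    all_reports: Sequence[CaseReport],
    cohort: Sequence[CaseReport],
    include_cohort: bool = False,
) -> list[CaseReport]:
    """The comparator set: the database window minus the cohort (default).

    Disproportionality is computed against the rest of the reporting
    database; whether the cohort's own reports stay in the comparator is a
    modelling choice, default excluded.
    """
    if include_cohort:
        return list(all_reports)
    cohort_ids = {r.caseid for r in cohort}
    return [r for r in all_reports if r.caseid not in cohort_ids]


def _report_terms(report: CaseReport, level: Level, meddra_map: Optional[MeddraMap]) -> frozenset[str]:
    pts = report.pt_set()
    if level == "PT":
        return pts
    if meddra_map is None:
        raise ValueError("SOC-level analysis requires a MeddraMap")
    return frozenset(normalize_term(meddra_map.soc_of(pt)) for pt in pts)


def build_contingency(
    cohort: Sequence[CaseReport],
    background: Sequence[CaseReport],
    term: str,
    level: Level = "PT",
    meddra_map: Optional[MeddraMap] = None,
) -> ContingencyTable:
    """Count the 2×2 for one term against the comparator background.

    ``background`` is the comparator set (by default construction elsewhere:
    all deduplicated reports in the window that are not in the cohort). The
    counting unit is the (report, term) pair with terms deduplicated within
    a report.
    """
    if not term:
        raise ValueError("term must be non-empty")
    key = normalize_term(term)
    a = b = c = d = 0
    for r in cohort:
        terms = _report_terms(r, level, meddra_map)
        if key in terms:
            a += 1
            b += len(terms) - 1
        else:
            b += len(terms)
    for r in background:
        terms = _report_terms(r, level, meddra_map)
        if key in terms:
            c += 1
            d += len(terms) - 1
        else:
            d += len(terms)
    return ContingencyTable(a, b, c, d, term=key, level=level,
                            flagged_absent=(a == 0 and c == 0))


def ror(table: ContingencyTable) -> RorEstimate:
    """Wald reporting odds ratio with 95% CI for a 2×2 table.

    Any zero cell makes the estimate incalculable (returned as NaNs with
    the flag set) rather than silently corrected.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return RorEstimate(math.nan, math.nan, math.nan, incalculable=True)
    estimate = (a * d) / (b * c)
    se_log = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(estimate)
    return RorEstimate(
        ror=estimate,
        ci_low=math.exp(log_ror - Z_95 * se_log),
        ci_high=math.exp(log_ror + Z_95 * se_log),
    )


def signal_criteria(result: SignalResult) -> bool:
    """The signal rule: lower 95% bound above 1 and at least two reports."""
    if math.isnan(result.ci_low):
        return False
    return result.ci_low > 1.0 and result.n >= 2


def _make_result(term: str, level: Level, table: ContingencyTable) -> SignalResult:
    est = ror(table)
    provisional = SignalResult(
        term=term, level=level, n=table.n,
        ror=est.ror, ci_low=est.ci_low, ci_high=est.ci_high,
        significant=False,
    )
    return replace(provisional, significant=signal_criteria(provisional))


def top_terms(
    cohort: Sequence[CaseReport],
    background: Sequence[CaseReport],
    level: Level = "PT",
    k: int = 50,
    exclusion: Iterable[str] = (),
    meddra_map: Optional[MeddraMap] = None,
    label_terms: Iterable[str] = (),
) -> list[SignalResult]:
    """Rank the cohort's terms by report count and attach ROR signals.

    Terms on the exclusion list (outcome terms, injection/infusion terms,
    disease-symptom terms — study-specific, supplied as data) are removed
    before ranking. Ranking is by N descending with alphabetical
    tie-breaking for determinism; at most ``k`` results are returned, each
    with ROR, CI, the significance decision, and expectedness against
    ``label_terms`` (empty label set ⇒ every significant signal is
    unexpected).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = {normalize_term(t) for t in exclusion}
    counts: dict[str, int] = {}
    for r in cohort:
        for term in _report_terms(r, level, meddra_map):
            if term not in excluded:
                counts[term] = counts.get(term, 0) + 1
    ranked = sorted(counts, key=lambda t: (-counts[t], t))[:k]
    results = [
        _make_result(term, level, build_contingency(cohort, background, term, level, meddra_map))
        for term in ranked
    ]
    return classify_expectedness(results, label_terms)


def classify_expectedness(
    results: Iterable[SignalResult], label_terms: Iterable[str]
) -> list[SignalResult]:
    """Split significant signals into label-listed vs unexpected.

    ``label_terms`` is the set of PTs appearing on the drug's current
    label; a significant signal absent from it is an unexpected signal.
    """
    labeled = {normalize_term(t) for t in label_terms}
    out: list[SignalResult] = []
    for r in results:
        if not r.significant:
            out.append(replace(r, expectedness="not_significant"))
        elif normalize_term(r.term) in labeled:
            out.append(replace(r, expectedness="labeled"))
        else:
            out.append(replace(r, expectedness="unexpected"))
    return out


def cross_drug_overlap(
    per_drug_results: Mapping[str, Sequence[SignalResult]],
) -> tuple[set[str], set[str]]:
    """Terms significant for every drug, split by expectedness.

    Returns ``(common_labeled, common_unexpected)``: the intersections
    across drugs of the label-listed significant terms and of the
    unexpected significant terms.
    """
    if len(per_drug_results) < 2:
        raise ValueError("cross-drug overlap needs results for at least two drugs")
    labeled_sets = []
    unexpected_sets = []
    for results in per_drug_results.values():
        labeled_sets.append({r.term for r in results if r.expectedness == "labeled"})
        unexpected_sets.append({r.term for r in results if r.expectedness == "unexpected"})
    common_labeled = set.intersection(*labeled_sets)
    common_unexpected = set.intersection(*unexpected_sets)
    return common_labeled, common_unexpected


def read_term_list(path: str | Path) -> list[str]:
    """Read a term list: one term per line, '#' starts a comment."""
    terms: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
    return terms


def signals_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Signal results as a DataFrame (term, level, n, ror, ci_low, ci_high, ...)."""
    return pd.DataFrame([
        {
            "term": r.term, "level": r.level, "n": r.n, "ror": r.ror,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "significant": r.significant, "expectedness": r.expectedness,
        }
        for r in results
    ])


def write_signal_table(results: Sequence[SignalResult], path: str | Path) -> None:
    """Write signal results as tab-delimited text."""
    frame = signals_to_frame(results)
    frame.to_csv(path, sep="\t", index=False)
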