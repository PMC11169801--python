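"""Clinical-characteristics summary of a report cohort.

Mirrors the standard pharmacovigilance descriptive table: sex, age band
(<18, 18–65, >65), reporter type, and reporting year, each with a missing
category, with percentages computed on the full cohort total (missing
included in the denominator) and printed half-up to one decimal.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .model import CaseReport

__all__ = ["CohortSummary", "summarize_cohort", "write_summary"]

MISSING = "missing"

#: Age-band convention: boundary ages 18 and 65 fall in the middle band
#: (closed interval), i.e. <18 means strictly younger than 18.
AGE_BANDS = ("<18", "18-65", ">65")


def percent_of(count: int, total: int) -> float:
    """Half-up percentage to one decimal, exact in decimal arithmetic."""
    if total == 0:
        return 0.0
    frac = Decimal(count * 100) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts and percentages per breakdown; counts in each sum to ``total``."""

    total: int
    by_sex: dict[str, tuple[int, float]] = field(default_factory=dict)
    by_age_band: dict[str, tuple[int, float]] = field(default_factory=dict)
    by_reporter: dict[str, tuple[int, float]] = field(default_factory=dict)
    by_year: dict[str, tuple[int, float]] = field(default_factory=dict)

    def breakdowns(self) -> Mapping[str, dict[str, tuple[int, float]]]:
        return {
            "sex": self.by_sex,
            "age_band": self.by_age_band,
            "reporter": self.by_reporter,
            "year": self.by_year,
        }


def _age_band(age: float | None) -> str:
    if age is None:
        return MISSING
    if age < 18:
        return "<18"
    if age <= 65:
        return "18-65"
    return ">65"


def _with_percent(counts: dict[str, int], total: int) -> dict[str, tuple[int, float]]:
    return {cat: (n, percent_of(n, total)) for cat, n in counts.items()}


def summarize_cohort(cohort: Iterable[CaseReport]) -> CohortSummary:
    """Tabulate sex, age band, reporter type, and reporting year for a cohort.

    The cohort is expected deduplicated. Every breakdown carries an explicit
    ``missing`` category and its counts sum to the cohort total; an empty
    cohort yields total 0 with empty breakdowns.
    """
    reports = list(cohort)
    total = len(reports)
    if total == 0:
        return CohortSummary(total=0)

    sex_counts = {"female": 0, "male": 0, MISSING: 0}
    age_counts = {band: 0 for band in AGE_BANDS}
    age_counts[MISSING] = 0
    rep_counts = {"medical": 0, "non_medical": 0, MISSING: 0}
    year_counts: dict[str, int] = {}

    for r in reports:
        sex_counts[r.sex if r.sex else MISSING] += 1
        age_counts[_age_band(r.age_years)] += 1
        rep_counts[r.reporter_class if r.reporter_class != "unknown" else MISSING] += 1
        year_counts[str(r.report_year)] = year_counts.get(str(r.report_year), 0) + 1

    return CohortSummary(
        total=total,
        by_sex=_with_percent(sex_counts, total),
        by_age_band=_with_percent(age_counts, total),
        by_reporter=_with_percent(rep_counts, total),
        by_year=_with_percent(dict(sorted(year_counts.items())), total),
    )


def write_summary(summary: CohortSummary, path: str | Path) -> None:
    """Write the summary as tab-delimited text (breakdown, category, count, percent)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["breakdown", "category", "count", "percent"])
        writer.writerow(["total", "", summary.total, ""])
        for name, table in summary.breakdowns().items():
            for category, (count, pct) in table.items():
                writer.writerow([name, category, count, pct])
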