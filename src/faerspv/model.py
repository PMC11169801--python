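"""Core record types shared across the pipeline.

Spontaneous-report databases carry partial and occasionally impossible
calendar dates, so dates are represented explicitly as :class:`PartialDate`
with a precision tag rather than being coerced to ``datetime`` (which would
silently lose the distinction between a missing day and a missing record).
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Optional

Precision = Literal["day", "month", "year", "missing", "invalid"]

DrugRole = Literal["PS", "SS", "C", "I"]

ReporterClass = Literal["medical", "non_medical", "unknown"]


def normalize_term(term: str) -> str:
    """Normalize a term (PT, SOC, or drug name) for matching.

    Trims, collapses internal whitespace, and case-folds. All term
    comparisons throughout the pipeline go through this function so that
    ``"FaTiGuE "`` and ``"fatigue"`` count as the same preferred term.
    """
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class PartialDate:
    """A date string of possibly reduced precision.

    ``ordinal_day`` is the proleptic-Gregorian ordinal (``date.toordinal``)
    and is present exactly when ``precision == "day"``.
    """

    raw: str
    precision: Precision
    ordinal_day: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.precision == "day") != (self.ordinal_day is not None):
            raise ValueError(
                "ordinal_day must be present iff precision is 'day' "
                f"(got precision={self.precision!r}, ordinal_day={self.ordinal_day!r})"
            )

    @property
    def is_day(self) -> bool:
        return self.precision == "day"


MISSING_DATE = PartialDate("", "missing")


def parse_date(raw: str) -> PartialDate:
    """Parse a FAERS-style date string into a :class:`PartialDate`.

    Accepted shapes: ``YYYYMMDD`` (day), ``YYYYMM`` (month), ``YYYY``
    (year). Empty or whitespace-only input is *missing*; anything else —
    including impossible calendar dates like ``20230231`` — is *invalid*.
    A ``YYYYMMDD`` string with a zero day component degrades to month
    precision, and a zero month component to year precision, matching how
    unknown components are sometimes encoded in the wild.

    This is a total function: it never raises.
    """
    s = raw.strip() if isinstance(raw, str) else ""
    if not s:
        return MISSING_DATE
    if not s.isdigit():
        return PartialDate(raw, "invalid")
    if len(s) == 4:
        return PartialDate(raw, "year") if s != "0000" else PartialDate(raw, "invalid")
    if len(s) == 6:
        month = int(s[4:6])
        if month == 0:
            return PartialDate(raw, "year")
        if 1 <= month <= 12:
            return PartialDate(raw, "month")
        return PartialDate(raw, "invalid")
    if len(s) == 8:
        year, month, day = int(s[:4]), int(s[4:6]), int(s[6:8])
        if month == 0:
            return PartialDate(raw, "year")
        if day == 0:
            if 1 <= month <= 12:
                return PartialDate(raw, "month")
            return PartialDate(raw, "invalid")
        try:
            d = _dt.date(year, month, day)
        except ValueError:
            return PartialDate(raw, "invalid")
        return PartialDate(raw, "day", d.toordinal())
    return PartialDate(raw, "invalid")


def format_ordinal(ordinal_day: int) -> str:
    """Inverse of :func:`parse_date` for day precision: ordinal -> YYYYMMDD."""
    return _dt.date.fromordinal(ordinal_day).strftime("%Y%m%d")


@dataclass(frozen=True)
class CaseReport:
    """One safety report after normalization.

    ``caseid`` is the stable case identifier (shared by successive versions
    of the same report), ``primaryid`` the version identifier, and
    ``fda_dt`` the agency receipt date as an orderable integer — the triple
    the deduplication rule operates on. ``reactions`` holds normalized
    preferred terms (possibly with within-report duplicates, which collapse
    at counting time). ``drugs`` is a sequence of ``(name, role)`` pairs
    where role is one of PS/SS/C/I.
    """

    caseid: int
    primaryid: int
    fda_dt: int
    sex: Optional[Literal["male", "female"]]
    age_years: Optional[float]
    occupation_code: Optional[str]
    reporter_class: ReporterClass
    drugs: tuple[tuple[str, str], ...]
    reactions: tuple[str, ...]
    therapy_start: PartialDate = MISSING_DATE
    event_date: PartialDate = MISSING_DATE
    report_year: int = 0

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError("a CaseReport must carry at least one reaction PT")
        if self.age_years is not None and not (0 <= self.age_years <= 150):
            raise ValueError(f"age_years out of range: {self.age_years}")

    def pt_set(self) -> frozenset[str]:
        """Distinct normalized PTs reported on this case."""
        return frozenset(normalize_term(p) for p in self.reactions)
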