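"""Report assembly, deduplication, drug matching, cohort selection, and MedDRA mapping.

FAERS cases accumulate versions: the same CASEID may appear with several
PRIMARYIDs as follow-up information arrives. The deduplication rule keeps,
for each case, the version with the latest FDA receipt date (FDA_DT) and,
among receipt-date ties, the largest PRIMARYID — i.e. always the most
recent version of the case.

The MedDRA dictionary is licensed and therefore not bundled: PT→SOC mapping
is consumed as a user-supplied two-column table (:class:`MeddraMap`), and
the synthetic-data module ships an invented vocabulary for tests.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .io import RawQuarter
from .model import (
    MISSING_DATE,
    CaseReport,
    PartialDate,
    ReporterClass,
    normalize_term,
    parse_date,
)

log = logging.getLogger(__name__)

__all__ = [
    "DrugQuery",
    "MeddraMap",
    "UNMAPPED_SOC",
    "assemble_reports",
    "deduplicate",
    "match_drug",
    "select_ps_cohort",
    "classify_reporter",
    "age_to_years",
    "map_pt_to_soc",
]

#: Reporter occupation codes treated as healthcare professionals / consumers.
#: MD physician, PH pharmacist, HP other health professional, OT other
#: professional; CN consumer, LW lawyer. Both sets are arguments of
#: :func:`classify_reporter` so studies can redraw the line.
MEDICAL_CODES = frozenset({"MD", "PH", "OT", "HP"})
NON_MEDICAL_CODES = frozenset({"CN", "LW"})

UNMAPPED_SOC = "UNMAPPED"

# FAERS age-unit codes -> multiplier to years.
_AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


@dataclass(frozen=True)
class DrugQuery:
    """A target drug and its retrieval synonyms (generic, brand, salt names)."""

    canonical_name: str
    synonyms: frozenset[str] = frozenset()

    def normalized_synonyms(self) -> frozenset[str]:
        names = {normalize_term(s) for s in self.synonyms}
        names.add(normalize_term(self.canonical_name))
        return frozenset(names)


@dataclass
class MeddraMap:
    """User-supplied PT → primary SOC mapping with case-insensitive lookup."""

    pt_to_soc: dict[str, str]

    def __post_init__(self) -> None:
        self.pt_to_soc = {normalize_term(pt): soc for pt, soc in self.pt_to_soc.items()}
        self._warned: set[str] = set()

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str = "\t") -> "MeddraMap":
        """Load from two-column delimited text (pt, soc); '#' starts a comment."""
        mapping: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                pt, soc = line.split(delimiter, 1)
                mapping[pt.strip()] = soc.strip()
        return cls(mapping)

    def soc_of(self, pt: str) -> str:
        key = normalize_term(pt)
        soc = self.pt_to_soc.get(key)
        if soc is None:
            if key not in self._warned:
                log.warning("PT %r has no SOC mapping; routed to %s", pt, UNMAPPED_SOC)
                self._warned.add(key)
            return UNMAPPED_SOC
        return soc


def map_pt_to_soc(pt: str, meddra_map: MeddraMap) -> str:
    """Primary SOC for a PT; unmapped PTs go to the ``UNMAPPED`` sentinel."""
    return meddra_map.soc_of(pt)


def classify_reporter(
    occupation_code: Optional[str],
    medical_codes: frozenset[str] = MEDICAL_CODES,
    non_medical_codes: frozenset[str] = NON_MEDICAL_CODES,
) -> ReporterClass:
    """Partition reporter occupation codes into medical / non-medical / unknown."""
    if not occupation_code:
        return "unknown"
    code = occupation_code.strip().upper()
    if code in medical_codes:
        return "medical"
    if code in non_medical_codes:
        return "non_medical"
    return "unknown"


def age_to_years(age_value, age_unit_code: Optional[str]) -> Optional[float]:
    """Convert a FAERS (AGE, AGE_COD) pair to years, or None.

    Unknown unit codes, non-numeric values, and results outside [0, 150]
    years yield None with a logged warning — an implausible age is treated
    as missing rather than poisoning the age-band summary.
    """
    if age_value is None or age_value == "":
        return None
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        log.warning("non-numeric age value %r treated as missing", age_value)
        return None
    unit = (age_unit_code or "YR").strip().upper()
    factor = _AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        log.warning("unknown age unit %r treated as missing", age_unit_code)
        return None
    years = value * factor
    if not (0.0 <= years <= 150.0):
        log.warning("age %s %s -> %.1f years out of range; treated as missing",
                    age_value, unit, years)
        return None
    return years


def match_drug(drug_name: str, query: DrugQuery) -> bool:
    """True iff the verbatim drug name matches any synonym as a whole word.

    Verbatim FAERS names carry dose and formulation suffixes
    (``"PATISIRAN SODIUM."``), so matching is word-boundary containment on
    normalized strings, not exact equality.
    """
    name = normalize_term(drug_name)
    for syn in query.normalized_synonyms():
        if re.search(rf"(?<!\w){re.escape(syn)}(?!\w)", name):
            return True
    return False


def _pick_therapy_start(raw_dates: Sequence[str]) -> PartialDate:
    """Earliest day-precision therapy start if any, else the first recorded date."""
    parsed = [parse_date(r) for r in raw_dates]
    day_dates = [p for p in parsed if p.is_day]
    if day_dates:
        return min(day_dates, key=lambda p: p.ordinal_day)
    return parsed[0] if parsed else MISSING_DATE


def assemble_reports(
    quarter: RawQuarter,
    medical_codes: frozenset[str] = MEDICAL_CODES,
    non_medical_codes: frozenset[str] = NON_MEDICAL_CODES,
) -> list[CaseReport]:
    """Join the four sub-tables into one :class:`CaseReport` per DEMO row.

    The event date comes from the DEMO record (EVENT_DT) and the therapy
    start from THER (earliest day-precision START_DT when several therapy
    rows exist). DEMO rows with unparseable identifiers or no reaction rows
    are skipped with a logged count — a safety report without an adverse
    event term is not analyzable by any downstream stage.
    """
    drugs_by_id: dict[str, list[tuple[str, str]]] = {}
    for row in quarter.drug_rows:
        drugs_by_id.setdefault(row["PRIMARYID"], []).append(
            (row["DRUGNAME"].strip(), row["ROLE_COD"].strip().upper())
        )
    reacs_by_id: dict[str, list[str]] = {}
    for row in quarter.reac_rows:
        reacs_by_id.setdefault(row["PRIMARYID"], []).append(normalize_term(row["PT"]))
    thers_by_id: dict[str, list[str]] = {}
    for row in quarter.ther_rows:
        thers_by_id.setdefault(row["PRIMARYID"], []).append(row["START_DT"])

    reports: list[CaseReport] = []
    n_skipped_ids = n_skipped_noreac = 0
    for row in quarter.demo_rows:
        try:
            primaryid = int(row["PRIMARYID"])
            caseid = int(row["CASEID"])
            fda_dt = int(row["FDA_DT"])
        except (KeyError, ValueError):
            n_skipped_ids += 1
            continue
        reactions = reacs_by_id.get(row["PRIMARYID"], [])
        if not reactions:
            n_skipped_noreac += 1
            continue
        sex_code = row.get("SEX", "").strip().upper()
        sex = {"M": "male", "F": "female"}.get(sex_code)
        occ = row.get("OCCP_COD", "").strip() or None
        reports.append(CaseReport(
            caseid=caseid,
            primaryid=primaryid,
            fda_dt=fda_dt,
            sex=sex,  # type: ignore[arg-type]
            age_years=age_to_years(row.get("AGE", ""), row.get("AGE_COD", "")),
            occupation_code=occ,
            reporter_class=classify_reporter(occ, medical_codes, non_medical_codes),
            drugs=tuple(drugs_by_id.get(row["PRIMARYID"], [])),
            reactions=tuple(reactions),
            therapy_start=_pick_therapy_start(thers_by_id.get(row["PRIMARYID"], [])),
            event_date=parse_date(row.get("EVENT_DT", "")),
            report_year=fda_dt // 10000,
        ))
    if n_skipped_ids:
        log.warning("skipped %d DEMO rows with unparseable identifiers", n_skipped_ids)
    if n_skipped_noreac:
        log.warning("skipped %d DEMO rows with no reaction PTs", n_skipped_noreac)
    return reports


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep one version per CASEID: latest FDA_DT, then largest PRIMARYID.

    Idempotent and order-independent; output is sorted by caseid. The
    degenerate tie on both FDA_DT and PRIMARYID cannot occur in real data
    (PRIMARYID is unique); if synthetic input produces it, the first-seen
    report is kept and a warning logged.
    """
    kept: dict[int, CaseReport] = {}
    for report in reports:
        incumbent = kept.get(report.caseid)
        if incumbent is None:
            kept[report.caseid] = report
            continue
        new_key = (report.fda_dt, report.primaryid)
        old_key = (incumbent.fda_dt, incumbent.primaryid)
        if new_key == old_key:
            log.warning("caseid %d: exact tie on (FDA_DT, PRIMARYID); keeping first seen",
                        report.caseid)
            continue
        if new_key > old_key:
            kept[report.caseid] = report
    return [kept[cid] for cid in sorted(kept)]


def select_ps_cohort(reports: Iterable[CaseReport], query: DrugQuery) -> list[CaseReport]:
    """Reports where the target drug appears with the primary-suspect (PS) role.

    Input is expected deduplicated, so the cohort size equals the count of
    unique caseids; a report with several matching PS rows still counts once.
    """
    return [
        r for r in reports
        if any(role == "PS" and match_drug(name, query) for name, role in r.drugs)
    ]
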