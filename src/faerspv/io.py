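"""Reading and writing FAERS-dialect quarterly tables and the normalized report table.

The quarterly ASCII release splits each quarter into four sub-tables —
DEMO (demographics), DRUG (drug rows with role codes), REAC (reaction
preferred terms), THER (therapy dates) — joined on PRIMARYID/CASEID and
delimited by ``$`` with a single header line and no quoting. The dialect is
declared as data (:class:`TableDialect`) so tests and other sources can use
different delimiters or column subsets.

Readers never silently drop input: malformed rows land in a rejects list
with machine-readable reasons, and child-table rows whose PRIMARYID has no
DEMO row are kept but flagged in a cross-reference report.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .model import CaseReport, PartialDate, parse_date

log = logging.getLogger(__name__)

__all__ = [
    "TableDialect",
    "FAERS_DIALECT",
    "Reject",
    "RawQuarter",
    "FaersFormatError",
    "read_quarter",
    "write_quarter_tables",
    "write_normalized",
    "read_normalized",
    "write_rejects",
]


class FaersFormatError(Exception):
    """Raised for fatal structural problems (missing file, header mismatch)."""


@dataclass(frozen=True)
class TableDialect:
    """Declares the delimiter and per-table column schema of a quarterly release.

    The default :data:`FAERS_DIALECT` lists the column subset this pipeline
    consumes; a file's header must match the declared set exactly
    (case-insensitive) or the reader fails fast naming the offending columns.
    """

    delimiter: str = "$"
    demo_columns: tuple[str, ...] = (
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE", "AGE_COD", "OCCP_COD",
    )
    drug_columns: tuple[str, ...] = ("PRIMARYID", "CASEID", "DRUGNAME", "ROLE_COD")
    reac_columns: tuple[str, ...] = ("PRIMARYID", "CASEID", "PT")
    ther_columns: tuple[str, ...] = ("PRIMARYID", "CASEID", "START_DT")

    def columns_for(self, table: str) -> tuple[str, ...]:
        return {
            "DEMO": self.demo_columns,
            "DRUG": self.drug_columns,
            "REAC": self.reac_columns,
            "THER": self.ther_columns,
        }[table]


FAERS_DIALECT = TableDialect()


@dataclass(frozen=True)
class Reject:
    """A row the reader could not use, with a machine-readable reason."""

    table: str
    line_no: int
    reason: str
    raw: str


@dataclass
class RawQuarter:
    """All rows of one quarter, unfiltered, plus rejects and referential flags."""

    demo_rows: list[dict[str, str]] = field(default_factory=list)
    drug_rows: list[dict[str, str]] = field(default_factory=list)
    reac_rows: list[dict[str, str]] = field(default_factory=list)
    ther_rows: list[dict[str, str]] = field(default_factory=list)
    rejects: list[Reject] = field(default_factory=list)
    orphans: dict[str, list[str]] = field(default_factory=dict)

    def rows_for(self, table: str) -> list[dict[str, str]]:
        return {
            "DEMO": self.demo_rows,
            "DRUG": self.drug_rows,
            "REAC": self.reac_rows,
            "THER": self.ther_rows,
        }[table]


def _read_table(
    path: Path, table: str, dialect: TableDialect, rejects: list[Reject]
) -> list[dict[str, str]]:
    if not path.exists():
        raise FaersFormatError(f"{table} file not found: {path}")
    columns = dialect.columns_for(table)
    rows: list[dict[str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FaersFormatError(f"{table} file {path} is empty (no header)")
        header = [c.strip().upper() for c in header_line.rstrip("\r\n").split(dialect.delimiter)]
        if set(header) != {c.upper() for c in columns}:
            missing = sorted({c.upper() for c in columns} - set(header))
            extra = sorted(set(header) - {c.upper() for c in columns})
            raise FaersFormatError(
                f"{table} header mismatch in {path}: missing={missing} unexpected={extra}"
            )
        index = [header.index(c.upper()) for c in columns]
        n_fields = len(header)
        for line_no, line in enumerate(fh, start=2):
            stripped = line.rstrip("\r\n")
            if not stripped:
                continue
            fields = stripped.split(dialect.delimiter)
            if len(fields) != n_fields:
                rejects.append(Reject(table, line_no, "field_count", stripped))
                continue
            rows.append({c: fields[i].strip() for c, i in zip(columns, index)})
    return rows


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    ther_path: str | Path,
    dialect: TableDialect = FAERS_DIALECT,
) -> RawQuarter:
    """Read one quarter's four sub-tables.

    Returns every well-formed row without filtering. Rows with the wrong
    field count are collected in ``rejects``; DRUG/REAC/THER rows whose
    PRIMARYID is absent from DEMO are kept and listed per table in
    ``orphans``. Missing files or header/schema mismatches raise
    :class:`FaersFormatError`.
    """
    rejects: list[Reject] = []
    quarter = RawQuarter(rejects=rejects)
    quarter.demo_rows = _read_table(Path(demo_path), "DEMO", dialect, rejects)
    quarter.drug_rows = _read_table(Path(drug_path), "DRUG", dialect, rejects)
    quarter.reac_rows = _read_table(Path(reac_path), "REAC", dialect, rejects)
    quarter.ther_rows = _read_table(Path(ther_path), "THER", dialect, rejects)

    demo_ids = {r["PRIMARYID"] for r in quarter.demo_rows}
    for table in ("DRUG", "REAC", "THER"):
        orphan_ids = sorted({r["PRIMARYID"] for r in quarter.rows_for(table)} - demo_ids)
        if orphan_ids:
            quarter.orphans[table] = orphan_ids
            log.warning("%s: %d primaryids have no DEMO row", table, len(orphan_ids))
    return quarter


def write_quarter_tables(
    quarter: RawQuarter, out_dir: str | Path, dialect: TableDialect = FAERS_DIALECT
) -> dict[str, Path]:
    """Write the four sub-tables of a quarter in the given dialect.

    Inverse of :func:`read_quarter` for well-formed quarters; used mainly to
    materialize synthetic quarters on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table in ("DEMO", "DRUG", "REAC", "THER"):
        columns = dialect.columns_for(table)
        path = out / f"{table}.txt"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(dialect.delimiter.join(columns) + "\n")
            for row in quarter.rows_for(table):
                fields = [str(row.get(c, "")) for c in columns]
                # "_EXTRA" marks an intentionally corrupt row (synthetic
                # malformation injection): the spare field breaks the field
                # count so readers exercise their rejects path.
                if "_EXTRA" in row:
                    fields.append(str(row["_EXTRA"]))
                fh.write(dialect.delimiter.join(fields) + "\n")
        paths[table] = path
    return paths


# ---------------------------------------------------------------------------
# Normalized report table (one row per report, nested fields as JSON cells)

_NORMALIZED_COLUMNS = (
    "caseid", "primaryid", "fda_dt", "sex", "age_years", "occupation_code",
    "reporter_class", "drugs", "reactions", "therapy_start", "event_date",
    "report_year",
)


def write_normalized(reports: Iterable[CaseReport], path: str | Path) -> None:
    """Write reports as tab-delimited text, one row per report.

    Drug and reaction lists are serialized as JSON cells (JSON escapes tabs
    and newlines, so the container stays a valid flat TSV); absent values
    are empty cells, never the string ``"NA"``. Round-trips exactly through
    :func:`read_normalized`.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_NORMALIZED_COLUMNS)
        for r in reports:
            writer.writerow([
                r.caseid,
                r.primaryid,
                r.fda_dt,
                r.sex or "",
                "" if r.age_years is None else repr(float(r.age_years)),
                r.occupation_code or "",
                r.reporter_class,
                json.dumps([[n, role] for n, role in r.drugs], ensure_ascii=False),
                json.dumps(list(r.reactions), ensure_ascii=False),
                r.therapy_start.raw,
                r.event_date.raw,
                r.report_year,
            ])


def read_normalized(path: str | Path) -> list[CaseReport]:
    """Read a normalized report table written by :func:`write_normalized`."""
    reports: list[CaseReport] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != _NORMALIZED_COLUMNS:
            raise FaersFormatError(f"unexpected normalized-table header in {path}: {header}")
        for row in reader:
            (caseid, primaryid, fda_dt, sex, age, occ, rep_class,
             drugs, reactions, ther, event, year) = row
            reports.append(CaseReport(
                caseid=int(caseid),
                primaryid=int(primaryid),
                fda_dt=int(fda_dt),
                sex=sex or None,  # type: ignore[arg-type]
                age_years=None if age == "" else float(age),
                occupation_code=occ or None,
                reporter_class=rep_class,  # type: ignore[arg-type]
                drugs=tuple((n, role) for n, role in json.loads(drugs)),
                reactions=tuple(json.loads(reactions)),
                therapy_start=parse_date(ther),
                event_date=parse_date(event),
                report_year=int(year),
            ))
    return reports


def write_rejects(rejects: Sequence[Reject], path: str | Path) -> None:
    """Write the rejects report as tab-delimited text."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["table", "line_no", "reason", "raw"])
        for rej in rejects:
            writer.writerow([rej.table, rej.line_no, rej.reason, rej.raw])
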