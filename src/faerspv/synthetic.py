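"""FAERS-like quarter generator with a known ground truth.

No public accession exists for the spontaneous-report snapshot this kind of
study analyzes, and the MedDRA dictionary is licensed, so the generator
emulates the *joint structure* of the four quarterly sub-tables with an
invented PT vocabulary and synthetic SOC assignments: deduplicatable case
versions sharing a CASEID, target-drug cohorts with planted drug–event
associations of known odds ratio, Weibull-distributed onset intervals,
partial and missing dates, and Table-2-like missingness of sex, age, and
reporter occupation. Every planted parameter is recorded in a
:class:`SyntheticTruth` manifest so each pipeline stage can be checked
against what was actually simulated.

Planting a signal: a background report carries the signal PT with base
probability q; a cohort report (of the right reporter stratum, when the
signal is stratum-specific) carries it with probability
p = ROR·q / (1 − q + ROR·q), so the report-level odds ratio of carrying
the PT equals the target ROR exactly. All other PTs are drawn from the
shared base-frequency vocabulary identically in cohort and background.

All randomness flows from a single integer seed through one NumPy
generator, in a fixed draw order, so output is byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import FAERS_DIALECT, RawQuarter, TableDialect, write_quarter_tables
from .model import normalize_term
from .preprocess import MeddraMap

__all__ = [
    "SignalSpec",
    "DrugSpec",
    "SimConfig",
    "SyntheticTruth",
    "SimulationError",
    "default_vocabulary",
    "default_config",
    "synthetic_meddra_map",
    "tune_signal_probability",
    "generate_quarter",
    "write_quarter",
    "simulate",
]


class SimulationError(Exception):
    """Raised for infeasible simulation configurations."""


# ---------------------------------------------------------------------------
# Invented PT vocabulary (deterministic, no licensed dictionary content)

_PREFIXES = (
    "hepatic", "renal", "cardiac", "neural", "dermal", "ocular", "gastric",
    "pulmonary", "vascular", "muscular", "skeletal", "immune", "endocrine",
    "haematic", "psychic", "auditory", "metabolic", "urinary", "lymphatic",
    "mucosal",
)
_SUFFIXES = (
    "tremor", "rash", "oedema", "spasm", "lassitude", "ache",
    "discolouration", "hypertrophy", "irritation", "numbness",
)


def default_vocabulary() -> tuple[tuple[str, ...], np.ndarray, dict[str, str]]:
    """(terms, base probabilities, PT→SOC map) for the invented vocabulary.

    200 two-word invented PTs with Zipf-like base frequencies; each prefix
    group maps to its own invented SOC, giving 20 synthetic organ classes.
    """
    terms = tuple(f"{p} {s}" for p in _PREFIXES for s in _SUFFIXES)
    weights = np.array([1.0 / (i + 3) for i in range(len(terms))])
    probs = weights / weights.sum()
    soc_map = {t: f"{t.split()[0]} system disorders" for t in terms}
    return terms, probs, soc_map


_BACKGROUND_DRUGS = tuple(f"comparatol-{i:02d}" for i in range(1, 31))
_MEDICAL_OCC = ("MD", "PH", "OT", "HP")
_NON_MEDICAL_OCC = ("CN", "LW")


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class SignalSpec:
    """One planted drug–event association.

    ``base_prob`` is the probability that a non-cohort report carries the
    PT; the in-cohort probability is tuned so the report-level odds ratio
    equals ``target_ror``. ``stratum`` restricts the planted excess to one
    reporter class ("all", "medical", or "non_medical"); other strata of
    the cohort report the PT at base rate.
    """

    pt: str
    target_ror: float
    base_prob: float = 0.01
    stratum: str = "all"


@dataclass(frozen=True)
class DrugSpec:
    """A target drug: synonyms, cohort size, planted signals, label terms, onset model."""

    name: str
    synonyms: tuple[str, ...]
    n_ps_reports: int
    signal_pts: tuple[SignalSpec, ...] = ()
    label_pts: tuple[str, ...] = ()
    weibull_shape: float = 1.0
    weibull_scale: float = 150.0
    first_year: int = 2018


def _default_drug_specs() -> tuple[DrugSpec, ...]:
    return (
        DrugSpec(
            name="patisiran",
            synonyms=("ALN-TTR02", "onpattro", "patisiran sodium"),
            n_ps_reports=2158,
            signal_pts=(
                SignalSpec("fatigue", 8.0, 0.01),
                SignalSpec("malaise", 3.0, 0.02),
                SignalSpec("vitamin a decreased", 6.0, 0.005),
            ),
            label_pts=("vitamin a decreased", "muscle spasms", "arthralgia", "dyspnoea"),
            weibull_shape=0.81,
            weibull_scale=325.0,
            first_year=2018,
        ),
        DrugSpec(
            name="vutrisiran",
            synonyms=("amvuttra", "vutrisiran sodium"),
            n_ps_reports=258,
            signal_pts=(
                SignalSpec("fall", 6.0, 0.01),
                SignalSpec("pain in extremity", 4.0, 0.01),
            ),
            label_pts=("vitamin a decreased", "arthralgia", "dyspnoea"),
            weibull_shape=1.48,
            weibull_scale=132.0,
            first_year=2022,
        ),
        DrugSpec(
            name="inotersen",
            synonyms=("inotersen sodium", "tegsedi"),
            n_ps_reports=1043,
            signal_pts=(
                SignalSpec("platelet count decreased", 12.0, 0.005),
                SignalSpec("malaise", 3.0, 0.02),
            ),
            label_pts=("platelet count decreased", "glomerulonephritis",
                       "vitamin a decreased", "arthralgia", "dyspnoea"),
            weibull_shape=0.81,
            weibull_scale=380.0,
            first_year=2018,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic quarter.

    Defaults emulate a three-drug TTR-inhibitor surveillance window
    (2018–2023): the three cohort sizes 2158/258/1043, Weibull onset models
    whose medians are 207/103/242 days, Table-2-like missingness of sex,
    age and occupation, a ~55/45 medical/non-medical reporter mix, and a
    15% duplicate-version rate. The background is 20,000 reports standing
    in for the full database at reduced scale.
    """

    n_background_reports: int = 20000
    drug_specs: tuple[DrugSpec, ...] = field(default_factory=_default_drug_specs)
    duplicate_rate: float = 0.15
    tie_fraction: float = 0.2  # share of duplicates with tied FDA_DT
    missing_sex: float = 0.55
    missing_age: float = 0.65
    missing_occupation: float = 0.005
    prob_male_given_known: float = 0.6
    mean_extra_pts: float = 1.5  # Poisson mean of PTs beyond the first
    start_precision_mix: tuple[float, float, float, float] = (0.55, 0.15, 0.05, 0.25)
    event_precision_mix: tuple[float, float, float, float] = (0.60, 0.10, 0.05, 0.25)
    reporter_medical_prob: float = 0.55
    background_onset_mean: float = 120.0
    year_range: tuple[int, int] = (2018, 2023)
    malformed_row_rate: float = 0.0  # injected DEMO rows with a broken field count
    seed: int = 0


def default_config(**overrides) -> SimConfig:
    """The default study conditions, with keyword overrides."""
    return dataclasses.replace(SimConfig(), **overrides)


def synthetic_meddra_map(config: Optional[SimConfig] = None) -> MeddraMap:
    """PT→SOC map covering the invented vocabulary plus any configured signal/label PTs."""
    _, _, soc_map = default_vocabulary()
    mapping = dict(soc_map)
    socs = sorted(set(soc_map.values()))
    extra = []
    if config is not None:
        for spec in config.drug_specs:
            extra.extend(s.pt for s in spec.signal_pts)
            extra.extend(spec.label_pts)
    for i, pt in enumerate(sorted({normalize_term(p) for p in extra})):
        mapping.setdefault(pt, socs[i % len(socs)])
    return MeddraMap(mapping)


def tune_signal_probability(base_pt_prob: float, target_ror: float) -> float:
    """In-cohort report probability giving odds(p)/odds(q) = target ROR.

    p = ROR·q / (1 − q + ROR·q); always in (0, 1) for q in (0, 1) and
    ROR > 0, so any positive target is feasible.
    """
    q = base_pt_prob
    if not (0.0 < q < 1.0):
        raise SimulationError(f"base_pt_prob must be in (0,1), got {q}")
    if target_ror <= 0:
        raise SimulationError(f"target_ror must be positive, got {target_ror}")
    return (target_ror * q) / (1.0 - q + target_ror * q)


# ---------------------------------------------------------------------------
# Truth manifest

@dataclass
class SyntheticTruth:
    """Everything planted in one generated quarter, sufficient to verify every stage."""

    seed: int
    n_background: int
    drugs: dict[str, dict]
    duplicates: list[dict]

    def cohort_caseids(self, drug: str) -> list[int]:
        return self.drugs[drug]["cohort_caseids"]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# Generation

_PRECISIONS = ("day", "month", "year", "missing")


def _degrade(ordinal: int, precision: str) -> str:
    if precision == "missing":
        return ""
    d = _dt.date.fromordinal(ordinal)
    if precision == "day":
        return d.strftime("%Y%m%d")
    if precision == "month":
        return d.strftime("%Y%m")
    return d.strftime("%Y")


def _validate(config: SimConfig) -> None:
    for mix_name in ("start_precision_mix", "event_precision_mix"):
        mix = getattr(config, mix_name)
        if len(mix) != 4 or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
            raise SimulationError(f"{mix_name} must be 4 non-negative shares summing to 1")
    for p_name in ("duplicate_rate", "tie_fraction", "missing_sex", "missing_age",
                   "missing_occupation", "reporter_medical_prob", "malformed_row_rate"):
        p = getattr(config, p_name)
        if not (0.0 <= p <= 1.0):
            raise SimulationError(f"{p_name} must be in [0,1], got {p}")
    for spec in config.drug_specs:
        if spec.weibull_shape <= 0 or spec.weibull_scale <= 0:
            raise SimulationError(f"{spec.name}: Weibull parameters must be positive")
        for sig in spec.signal_pts:
            p = tune_signal_probability(sig.base_prob, sig.target_ror)  # raises if infeasible
            if not (0.0 < p < 1.0):
                raise SimulationError(
                    f"infeasible target ROR for PT {sig.pt!r}: required probability {p}")
            if sig.stratum not in ("all", "medical", "non_medical"):
                raise SimulationError(f"unknown stratum {sig.stratum!r} for PT {sig.pt!r}")


def generate_quarter(config: SimConfig) -> tuple[RawQuarter, SyntheticTruth]:
    """Generate one synthetic quarter and its truth manifest.

    Reports are laid out as one background block followed by one block per
    target drug; duplicate case versions (a clone with a strictly newer
    FDA_DT, or a tied FDA_DT with a larger PRIMARYID to exercise the
    tie-break) are appended after all originals. Fully reproducible from
    ``config.seed``.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)
    terms, probs, _ = default_vocabulary()
    n_terms = len(terms)

    specs = config.drug_specs
    block_sizes = [config.n_background_reports] + [s.n_ps_reports for s in specs]
    n_total = sum(block_sizes)
    drug_of = np.full(n_total, -1, dtype=int)
    offset = config.n_background_reports
    for j, spec in enumerate(specs):
        drug_of[offset:offset + spec.n_ps_reports] = j
        offset += spec.n_ps_reports

    # --- pre-draw every random stream in a fixed order ------------------
    occ_missing = rng.random(n_total) < config.missing_occupation
    is_medical = rng.random(n_total) < config.reporter_medical_prob
    occ_pick_med = rng.integers(0, len(_MEDICAL_OCC), n_total)
    occ_pick_non = rng.integers(0, len(_NON_MEDICAL_OCC), n_total)
    sex_missing = rng.random(n_total) < config.missing_sex
    sex_male = rng.random(n_total) < config.prob_male_given_known
    age_missing = rng.random(n_total) < config.missing_age
    age_vals = np.clip(np.round(rng.normal(60.0, 15.0, n_total)), 18, 90).astype(int)
    n_pts = 1 + rng.poisson(config.mean_extra_pts, n_total)
    pt_draws = rng.choice(n_terms, size=int(n_pts.sum()), p=probs)
    pt_bounds = np.concatenate([[0], np.cumsum(n_pts)])
    start_u = rng.random(n_total)
    onset_delta = np.empty(n_total)
    onset_delta[:block_sizes[0]] = rng.exponential(config.background_onset_mean, block_sizes[0])
    offset = block_sizes[0]
    for spec in specs:
        onset_delta[offset:offset + spec.n_ps_reports] = (
            spec.weibull_scale * rng.weibull(spec.weibull_shape, spec.n_ps_reports))
        offset += spec.n_ps_reports
    report_delay = rng.integers(7, 120, n_total)
    synonym_pick = rng.random(n_total)
    has_concomitant = rng.random(n_total) < 0.3
    concomitant_pick = rng.integers(0, len(_BACKGROUND_DRUGS), n_total)
    bg_drug_pick = rng.integers(0, len(_BACKGROUND_DRUGS), n_total)
    start_precision = rng.choice(4, n_total, p=config.start_precision_mix)
    event_precision = rng.choice(4, n_total, p=config.event_precision_mix)
    signal_u = {
        (j, s): rng.random(n_total)
        for j, spec in enumerate(specs) for s, _ in enumerate(spec.signal_pts)
    }
    dup_mask = rng.random(n_total) < config.duplicate_rate
    tie_mask = rng.random(n_total) < config.tie_fraction
    dup_delay = rng.integers(1, 30, n_total)
    malformed = rng.random(n_total) < config.malformed_row_rate

    tuned = {
        (j, s): tune_signal_probability(sig.base_prob, sig.target_ror)
        for j, spec in enumerate(specs) for s, sig in enumerate(spec.signal_pts)
    }

    y0, y1 = config.year_range
    window_end = _dt.date(y1, 9, 30).toordinal()
    receipt_end = _dt.date(y1, 12, 31).toordinal()  # receipt dates stay in-window
    base_ord = {-1: _dt.date(y0, 1, 1).toordinal()}
    for j, spec in enumerate(specs):
        base_ord[j] = _dt.date(max(y0, spec.first_year), 1, 1).toordinal()

    quarter = RawQuarter()
    truth_drugs = {
        spec.name: {
            "n_ps_reports": spec.n_ps_reports,
            "cohort_caseids": [],
            "weibull_shape": spec.weibull_shape,
            "weibull_scale": spec.weibull_scale,
            "label_pts": [normalize_term(t) for t in spec.label_pts],
            "signals": [
                {
                    "pt": normalize_term(sig.pt),
                    "target_ror": sig.target_ror,
                    "base_prob": sig.base_prob,
                    "cohort_prob": tuned[(j, s)],
                    "stratum": sig.stratum,
                }
                for s, sig in enumerate(spec.signal_pts)
            ],
        }
        for j, spec in enumerate(specs)
    }
    duplicates: list[dict] = []
    clone_rows: dict[str, list[dict[str, str]]] = {"DEMO": [], "DRUG": [], "REAC": [], "THER": []}
    n_malformed = 0

    for i in range(n_total):
        caseid = 1_000_001 + i
        primaryid = caseid * 100 + 1
        j = int(drug_of[i])

        if occ_missing[i]:
            occ = ""
        elif is_medical[i]:
            occ = _MEDICAL_OCC[occ_pick_med[i]]
        else:
            occ = _NON_MEDICAL_OCC[occ_pick_non[i]]
        reporter = "medical" if (occ and is_medical[i]) else ("non_medical" if occ else "unknown")
        sex = "" if sex_missing[i] else ("M" if sex_male[i] else "F")
        age = "" if age_missing[i] else str(age_vals[i])
        age_cod = "" if age_missing[i] else "YR"

        start_ord = base_ord[j] + int(start_u[i] * (window_end - base_ord[j]))
        event_ord = start_ord + int(round(onset_delta[i]))
        fda_ord = min(event_ord + int(report_delay[i]), receipt_end)
        fda_dt = _dt.date.fromordinal(fda_ord).strftime("%Y%m%d")

        pts = list(dict.fromkeys(terms[idx] for idx in pt_draws[pt_bounds[i]:pt_bounds[i + 1]]))
        for (jj, s), u in signal_u.items():
            sig = specs[jj].signal_pts[s]
            in_stratum = sig.stratum == "all" or sig.stratum == reporter
            p = tuned[(jj, s)] if (jj == j and in_stratum) else sig.base_prob
            pt = normalize_term(sig.pt)
            if u[i] < p and pt not in pts:
                pts.append(pt)

        if j >= 0:
            spec = specs[j]
            names = [spec.name] + list(spec.synonyms)
            drug_name = names[int(synonym_pick[i] * len(names))].upper()
            drug_rows = [(drug_name, "PS")]
            truth_drugs[spec.name]["cohort_caseids"].append(caseid)
        else:
            drug_rows = [(_BACKGROUND_DRUGS[bg_drug_pick[i]].upper(), "PS")]
        if has_concomitant[i]:
            drug_rows.append((_BACKGROUND_DRUGS[concomitant_pick[i]].upper(), "C"))

        start_raw = _degrade(start_ord, _PRECISIONS[start_precision[i]])
        event_raw = _degrade(event_ord, _PRECISIONS[event_precision[i]])
        n_malformed += int(malformed[i])

        pid = str(primaryid)
        demo_row = {
            "PRIMARYID": pid, "CASEID": str(caseid), "FDA_DT": fda_dt,
            "EVENT_DT": event_raw, "SEX": sex, "AGE": age, "AGE_COD": age_cod,
            "OCCP_COD": occ,
        }
        quarter.demo_rows.append(demo_row)
        for name, role in drug_rows:
            quarter.drug_rows.append(
                {"PRIMARYID": pid, "CASEID": str(caseid), "DRUGNAME": name, "ROLE_COD": role})
        for pt in pts:
            quarter.reac_rows.append({"PRIMARYID": pid, "CASEID": str(caseid), "PT": pt})
        quarter.ther_rows.append(
            {"PRIMARYID": pid, "CASEID": str(caseid), "START_DT": start_raw})

        if dup_mask[i]:
            clone_pid = str(caseid * 100 + 2)
            if tie_mask[i]:
                clone_fda = fda_dt
            else:
                clone_fda = _dt.date.fromordinal(
                    min(fda_ord + int(dup_delay[i]), receipt_end)).strftime("%Y%m%d")
            tie = clone_fda == fda_dt  # receipt-end clipping can force a tie
            clone_demo = dict(demo_row, PRIMARYID=clone_pid, FDA_DT=clone_fda)
            clone_rows["DEMO"].append(clone_demo)
            for name, role in drug_rows:
                clone_rows["DRUG"].append(
                    {"PRIMARYID": clone_pid, "CASEID": str(caseid), "DRUGNAME": name,
                     "ROLE_COD": role})
            for pt in pts:
                clone_rows["REAC"].append(
                    {"PRIMARYID": clone_pid, "CASEID": str(caseid), "PT": pt})
            clone_rows["THER"].append(
                {"PRIMARYID": clone_pid, "CASEID": str(caseid), "START_DT": start_raw})
            duplicates.append({
                "caseid": caseid,
                "kept_primaryid": int(clone_pid),
                "tie_on_fda_dt": tie,
            })

    quarter.demo_rows.extend(clone_rows["DEMO"])
    quarter.drug_rows.extend(clone_rows["DRUG"])
    quarter.reac_rows.extend(clone_rows["REAC"])
    quarter.ther_rows.extend(clone_rows["THER"])

    # Malformation injection: extra corrupt DEMO rows (wrong field count on
    # disk) with caseids outside the report range, so re-ingest sees them in
    # the rejects report without losing any planted report. In memory they
    # carry no reaction rows and are skipped at assembly.
    for m in range(n_malformed):
        quarter.demo_rows.append({
            "PRIMARYID": str(900_000_001 + m), "CASEID": str(9_000_001 + m),
            "FDA_DT": f"{y1}0101", "EVENT_DT": "", "SEX": "", "AGE": "",
            "AGE_COD": "", "OCCP_COD": "", "_EXTRA": "corrupt",
        })

    truth = SyntheticTruth(
        seed=config.seed,
        n_background=config.n_background_reports,
        drugs=truth_drugs,
        duplicates=duplicates,
    )
    return quarter, truth


def write_quarter(
    quarter: RawQuarter,
    truth: SyntheticTruth,
    out_dir: str | Path,
    dialect: TableDialect = FAERS_DIALECT,
) -> dict[str, Path]:
    """Write the quarter's four tables plus the truth manifest (truth.json)."""
    out = Path(out_dir)
    paths = write_quarter_tables(quarter, out, dialect)
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json(), encoding="utf-8")
    paths["TRUTH"] = truth_path
    return paths


def simulate(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a quarter under ``config`` and write it to ``out_dir``."""
    quarter, truth = generate_quarter(config)
    return write_quarter(quarter, truth, out_dir)
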