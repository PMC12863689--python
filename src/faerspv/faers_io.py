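"""Reading, validating and joining FAERS-style quarterly ASCII tables.

FAERS quarters are distributed as "$"-delimited text files with no quoting:
DEMO (one row per report), DRUG, REAC, OUTC, THER and INDI (many rows per
report, keyed by PRIMARYID).  This module parses that dialect defensively —
short rows are right-padded, rows with embedded "$" beyond the header arity
keep their first N fields and are counted as malformed — and joins the six
tables into per-report :class:`ReportCase` bundles.

Files are decoded as Latin-1 with replacement: legacy quarters contain
non-UTF-8 bytes and robustness matters more than strictness here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from faerspv.dates import ParsedDate, parse_date

logger = logging.getLogger(__name__)

DELIMITER = "$"
ENCODING = "latin-1"

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

# FAERS age-unit codes -> factor converting the stored number to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WS = re.compile(r"\s+")


def normalize_term(text: str) -> str:
    """Case-insensitive, whitespace-collapsed form used for all term matching."""
    return _WS.sub(" ", (text or "").strip()).lower()


def age_in_years(age: str, age_cod: str) -> Optional[float]:
    """Convert a FAERS AGE/AGE_COD pair to years; unknown unit or bad number -> None."""
    text = (age or "").strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    unit = (age_cod or "").strip().upper() or "YR"
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        return None
    return value * factor


# ---------------------------------------------------------------------------
# record types


@dataclass(slots=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: ParsedDate
    event_dt: ParsedDate
    age: str = ""
    age_cod: str = ""
    sex: str = ""  # "M", "F" or "" (unknown)
    occr_country: str = ""

    @property
    def age_years(self) -> Optional[float]:
        return age_in_years(self.age, self.age_cod)


@dataclass(slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: str
    role_cod: str
    drugname: str
    prod_ai: str = ""


@dataclass(slots=True)
class ReactionRecord:
    primaryid: str
    pt: str


@dataclass(slots=True)
class OutcomeRecord:
    primaryid: str
    outc_cod: str


@dataclass(slots=True)
class TherapyRecord:
    primaryid: str
    dsg_drug_seq: str
    start_dt: ParsedDate


@dataclass(slots=True)
class IndicationRecord:
    primaryid: str
    indi_drug_seq: str
    indi_pt: str


@dataclass(slots=True)
class ReportCase:
    """One report with all child records joined on PRIMARYID.

    Reactions are deduplicated to the unique PT set on construction (first
    spelling wins, order of first appearance preserved): a report listing the
    same PT twice contributes a single counting unit downstream.
    """

    demo: DemoRecord
    drugs: List[DrugRecord] = field(default_factory=list)
    reactions: List[ReactionRecord] = field(default_factory=list)
    outcomes: List[OutcomeRecord] = field(default_factory=list)
    therapies: List[TherapyRecord] = field(default_factory=list)
    indications: List[IndicationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: List[ReactionRecord] = []
        for r in self.reactions:
            key = normalize_term(r.pt)
            if key and key not in seen:
                seen.add(key)
                unique.append(r)
        self.reactions = unique

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def pts(self) -> List[str]:
        """Unique reaction PTs, original spelling, order of first appearance."""
        return [r.pt.strip() for r in self.reactions]


# ---------------------------------------------------------------------------
# table schemas

#: canonical header names; legacy (pre-2012) aliases are folded in on read
COLUMN_ALIASES = {
    "ISR": "PRIMARYID",
    "CASE": "CASEID",
    "GNDR_COD": "SEX",
}

MANDATORY_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "DEMO": ("PRIMARYID", "CASEID", "FDA_DT"),
    "DRUG": ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
    "REAC": ("PRIMARYID", "PT"),
    "OUTC": ("PRIMARYID", "OUTC_COD"),
    "THER": ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT"),
    "INDI": ("PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"),
}

OPTIONAL_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "DEMO": ("EVENT_DT", "AGE", "AGE_COD", "SEX", "OCCR_COUNTRY"),
    "DRUG": ("PROD_AI",),
    "REAC": (),
    "OUTC": (),
    "THER": (),
    "INDI": (),
}

#: header written by write_tables, and the synthetic generator's dialect
WRITE_COLUMNS: Dict[str, Tuple[str, ...]] = {
    kind: MANDATORY_COLUMNS[kind] + OPTIONAL_COLUMNS[kind] for kind in MANDATORY_COLUMNS
}


class SchemaError(ValueError):
    """A table file is missing a mandatory column for its kind."""


@dataclass
class TableRead:
    """Result of reading one table: records plus parse accounting."""

    kind: str
    records: list
    extra_columns: Dict[str, List[str]] = field(default_factory=dict)
    n_data_lines: int = 0
    n_malformed: int = 0


def _make_record(kind: str, row: Dict[str, str]):
    if kind == "DEMO":
        sex = row.get("SEX", "").strip().upper()
        return DemoRecord(
            primaryid=row["PRIMARYID"].strip(),
            caseid=row["CASEID"].strip(),
            fda_dt=parse_date(row["FDA_DT"]),
            event_dt=parse_date(row.get("EVENT_DT", "")),
            age=row.get("AGE", "").strip(),
            age_cod=row.get("AGE_COD", "").strip(),
            sex=sex if sex in ("M", "F") else "",
            occr_country=row.get("OCCR_COUNTRY", "").strip(),
        )
    if kind == "DRUG":
        return DrugRecord(
            primaryid=row["PRIMARYID"].strip(),
            drug_seq=row["DRUG_SEQ"].strip(),
            role_cod=row["ROLE_COD"].strip().upper(),
            drugname=row["DRUGNAME"].strip(),
            prod_ai=row.get("PROD_AI", "").strip(),
        )
    if kind == "REAC":
        return ReactionRecord(primaryid=row["PRIMARYID"].strip(), pt=row["PT"].strip())
    if kind == "OUTC":
        return OutcomeRecord(
            primaryid=row["PRIMARYID"].strip(), outc_cod=row["OUTC_COD"].strip().upper()
        )
    if kind == "THER":
        return TherapyRecord(
            primaryid=row["PRIMARYID"].strip(),
            dsg_drug_seq=row["DSG_DRUG_SEQ"].strip(),
            start_dt=parse_date(row["START_DT"]),
        )
    if kind == "INDI":
        return IndicationRecord(
            primaryid=row["PRIMARYID"].strip(),
            indi_drug_seq=row["INDI_DRUG_SEQ"].strip(),
            indi_pt=row["INDI_PT"].strip(),
        )
    raise ValueError(f"unknown table kind {kind!r}")


def read_table(path: str | Path, table_kind: str) -> TableRead:
    """Read one "$"-delimited FAERS table file.

    The first line is the header.  Short data lines are right-padded with
    blanks; lines with more fields than the header keep their first N fields
    and are counted as malformed (logged, never fatal).  Columns outside the
    known schema are preserved verbatim in ``extra_columns``.

    Raises :class:`SchemaError` if a mandatory column for ``table_kind`` is
    absent from the header.
    """
    kind = table_kind.upper()
    if kind not in MANDATORY_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    with path.open("r", encoding=ENCODING, errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, no header")
        header = [
            COLUMN_ALIASES.get(h.strip().upper(), h.strip().upper())
            for h in header_line.rstrip("\r\n").split(DELIMITER)
        ]
        missing = [c for c in MANDATORY_COLUMNS[kind] if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: {kind} table missing mandatory column(s) {', '.join(missing)}"
            )
        known = set(MANDATORY_COLUMNS[kind]) | set(OPTIONAL_COLUMNS[kind])
        extra_names = [c for c in header if c not in known]
        arity = len(header)
        result = TableRead(kind=kind, records=[], extra_columns={c: [] for c in extra_names})
        for line in fh:
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split(DELIMITER)
            result.n_data_lines += 1
            if len(fields) > arity:
                result.n_malformed += 1
                logger.warning(
                    "%s: line with %d fields exceeds header arity %d; "
                    "keeping first %d fields",
                    path.name,
                    len(fields),
                    arity,
                    arity,
                )
                fields = fields[:arity]
            elif len(fields) < arity:
                fields = fields + [""] * (arity - len(fields))
            row = dict(zip(header, fields))
            for c in extra_names:
                result.extra_columns[c].append(row[c])
            result.records.append(_make_record(kind, row))
    if result.n_data_lines == 0:
        logger.warning("%s: header-only file, no data lines", path.name)
    return result


def read_quarter_dir(directory: str | Path) -> Dict[str, list]:
    """Read every recognisable FAERS table file in a directory.

    Files are matched by kind prefix (DEMO*.txt, DRUG*.txt, ...).  Multiple
    quarters of the same kind are pooled in file-name order.  Returns a dict
    mapping kind to the pooled record list; kinds with no file are absent.
    """
    directory = Path(directory)
    tables: Dict[str, list] = {}
    for kind in MANDATORY_COLUMNS:
        paths = sorted(directory.glob(f"{kind}*.txt")) + sorted(
            directory.glob(f"{kind.lower()}*.txt")
        )
        records: list = []
        for p in paths:
            records.extend(read_table(p, kind).records)
        if paths:
            tables[kind] = records
    return tables


@dataclass
class JoinResult:
    cases: List[ReportCase]
    orphan_counts: Dict[str, int] = field(default_factory=dict)


def join_cases(tables: Dict[str, list]) -> JoinResult:
    """Join per-kind record lists into one :class:`ReportCase` per DEMO row.

    DEMO must be present; other tables are optional.  Child records whose
    PRIMARYID has no DEMO row are dropped and counted per kind.  A duplicate
    PRIMARYID within DEMO (after deduplication) is a hard error.
    """
    demos = tables.get("DEMO")
    if demos is None:
        raise ValueError("join_cases requires a DEMO table")
    by_id: Dict[str, ReportCase] = {}
    for demo in demos:
        if demo.primaryid in by_id:
            raise ValueError(f"duplicate PRIMARYID {demo.primaryid!r} in DEMO")
        by_id[demo.primaryid] = ReportCase(demo=demo)
    orphans: Dict[str, int] = {}
    attach = {
        "DRUG": "drugs",
        "REAC": "reactions",
        "OUTC": "outcomes",
        "THER": "therapies",
        "INDI": "indications",
    }
    for kind, attr in attach.items():
        n_orphan = 0
        for rec in tables.get(kind, []):
            case = by_id.get(rec.primaryid)
            if case is None:
                n_orphan += 1
                continue
            getattr(case, attr).append(rec)
        orphans[kind] = n_orphan
        if n_orphan:
            logger.info("join_cases: dropped %d orphan %s rows", n_orphan, kind)
    # re-apply within-report PT dedup now that reactions are attached
    cases = []
    for case in by_id.values():
        case.__post_init__()
        cases.append(case)
    return JoinResult(cases=cases, orphan_counts=orphans)


# ---------------------------------------------------------------------------
# writing (round-trip support and the synthetic generator's output path)


def _row_for(kind: str, rec) -> List[str]:
    if kind == "DEMO":
        return [
            rec.primaryid,
            rec.caseid,
            rec.fda_dt.raw,
            rec.event_dt.raw,
            rec.age,
            rec.age_cod,
            rec.sex,
            rec.occr_country,
        ]
    if kind == "DRUG":
        return [rec.primaryid, rec.drug_seq, rec.role_cod, rec.drugname, rec.prod_ai]
    if kind == "REAC":
        return [rec.primaryid, rec.pt]
    if kind == "OUTC":
        return [rec.primaryid, rec.outc_cod]
    if kind == "THER":
        return [rec.primaryid, rec.dsg_drug_seq, rec.start_dt.raw]
    if kind == "INDI":
        return [rec.primaryid, rec.indi_drug_seq, rec.indi_pt]
    raise ValueError(kind)


def write_tables(
    tables: Dict[str, Iterable], directory: str | Path, suffix: str = "SIM"
) -> Dict[str, Path]:
    """Write per-kind record lists as "$"-delimited files readable by read_table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for kind, records in tables.items():
        kind = kind.upper()
        path = directory / f"{kind}{suffix}.txt"
        with path.open("w", encoding=ENCODING, errors="replace", newline="\n") as fh:
            fh.write(DELIMITER.join(WRITE_COLUMNS[kind]) + "\n")
            for rec in records:
                fh.write(DELIMITER.join(_row_for(kind, rec)) + "\n")
        paths[kind] = path
    return paths


def cases_to_tables(cases: Sequence[ReportCase]) -> Dict[str, list]:
    """Explode ReportCases back into per-kind record lists (round-trip helper)."""
    tables: Dict[str, list] = {k: [] for k in MANDATORY_COLUMNS}
    for case in cases:
        tables["DEMO"].append(case.demo)
        tables["DRUG"].extend(case.drugs)
        tables["REAC"].extend(case.reactions)
        tables["OUTC"].extend(case.outcomes)
        tables["THER"].extend(case.therapies)
        tables["INDI"].extend(case.indications)
    return tables
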