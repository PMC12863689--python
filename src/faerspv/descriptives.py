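"""Descriptive surfaces: demographics, seriousness/outcomes, time-to-onset.

Conventions follow common spontaneous-report practice: every facet (sex, age
band, country, seriousness, TTO bin) partitions the cohort, percentages are
of total cohort reports to two decimals, a report is serious when it carries
at least one outcome record, and its primary outcome is the worst under
DE > LT > HO > DS > CA > RI > OT.  Time-to-onset is event onset minus the
earliest therapy start of the matched target drug, in days, and requires
both dates at day precision; negative or uncomputable values are
missing/invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from faerspv.cohort import CohortSpec, match_drug
from faerspv.faers_io import OUTCOME_CODES, ReportCase
from faerspv.signal_stats import proportion_pct

logger = logging.getLogger(__name__)

#: worst-first severity ranking of FAERS outcome codes
OUTCOME_RANKING = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening condition",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious medically important event",
}

TTO_BINS = ("d0_90", "d91_180", "d181_360", "d_gt360", "missing_invalid")

TTO_BIN_LABELS = {
    "d0_90": "0-90d",
    "d91_180": "91-180d",
    "d181_360": "181-360d",
    "d_gt360": ">360d",
    "missing_invalid": "Missing or invalid",
}


@dataclass(slots=True)
class TtoRecord:
    primaryid: str
    tto_days: Optional[int]
    bin: str


@dataclass
class OutcomeSummary:
    serious_count: int
    non_serious_count: int
    per_outcome: Dict[str, int]  # code -> count
    mode: str  # "worst" or "occurrence"

    @property
    def total(self) -> int:
        return self.serious_count + self.non_serious_count


# ---------------------------------------------------------------------------
# demographics


def _age_band(years: Optional[float]) -> str:
    if years is None:
        return "Not specified"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64"
    return ">=65"


def demographics_table(cohort: Sequence[ReportCase], top_k_countries: int = 5) -> pd.DataFrame:
    """Tidy facet/level/count/pct table for sex, age bands and countries.

    Countries keep the top-k by count plus "Other countries"; blanks are
    "Not specified".  Percentages are of total cohort reports (2 decimals),
    so each facet's cells sum to the cohort size.
    """
    total = len(cohort)
    sex_counts = {"Male": 0, "Female": 0, "Not specified": 0}
    age_counts = {"<18": 0, "18-64": 0, ">=65": 0, "Not specified": 0}
    country_counts: Dict[str, int] = {}
    for case in cohort:
        sex = case.demo.sex
        sex_counts["Male" if sex == "M" else "Female" if sex == "F" else "Not specified"] += 1
        age_counts[_age_band(case.demo.age_years)] += 1
        country = case.demo.occr_country or "Not specified"
        country_counts[country] = country_counts.get(country, 0) + 1
    rows: List[dict] = []
    for level, n in sex_counts.items():
        rows.append({"facet": "sex", "level": level, "count": n})
    for level, n in age_counts.items():
        rows.append({"facet": "age", "level": level, "count": n})
    named = {k: v for k, v in country_counts.items() if k != "Not specified"}
    top = sorted(named.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k_countries]
    top_names = {k for k, _ in top}
    other = sum(v for k, v in named.items() if k not in top_names)
    for level, n in top:
        rows.append({"facet": "country", "level": level, "count": n})
    rows.append(
        {
            "facet": "country",
            "level": "Not specified",
            "count": country_counts.get("Not specified", 0),
        }
    )
    rows.append({"facet": "country", "level": "Other countries", "count": other})
    df = pd.DataFrame(rows, columns=["facet", "level", "count"])
    df["pct"] = [proportion_pct(n, total) for n in df["count"]]
    return df


# ---------------------------------------------------------------------------
# seriousness


def classify_serious(case: ReportCase) -> Tuple[bool, Optional[str]]:
    """(is_serious, primary outcome code).

    Serious iff the report has at least one outcome record; the primary
    outcome is the worst-ranked code.  Unknown codes count as OT with a
    warning.  Monotone: adding outcome records never un-seriouses a report.
    """
    if not case.outcomes:
        return False, None
    codes = set()
    for rec in case.outcomes:
        code = rec.outc_cod
        if code not in OUTCOME_CODES:
            logger.warning("unknown OUTC_COD %r treated as OT", code)
            code = "OT"
        codes.add(code)
    for code in OUTCOME_RANKING:
        if code in codes:
            return True, code
    return True, "OT"


def outcome_summary(cohort: Sequence[ReportCase], mode: str = "worst") -> OutcomeSummary:
    """Outcome tabulation in per-report worst-case or per-occurrence mode.

    ``worst`` counts each serious report once under its primary outcome (the
    per-outcome counts then sum to the serious count); ``occurrence`` counts
    every outcome row, so the sum can exceed the number of reports.
    """
    if mode not in ("worst", "occurrence"):
        raise ValueError(f"unknown outcome mode {mode!r}")
    per_outcome = {code: 0 for code in OUTCOME_RANKING}
    serious = 0
    for case in cohort:
        is_serious, primary = classify_serious(case)
        if not is_serious:
            continue
        serious += 1
        if mode == "worst":
            per_outcome[primary] += 1
        else:
            for rec in case.outcomes:
                code = rec.outc_cod if rec.outc_cod in OUTCOME_CODES else "OT"
                per_outcome[code] += 1
    return OutcomeSummary(
        serious_count=serious,
        non_serious_count=len(cohort) - serious,
        per_outcome=per_outcome,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# time-to-onset


def _bin_tto(days: int) -> str:
    if days <= 90:
        return "d0_90"
    if days <= 180:
        return "d91_180"
    if days <= 360:
        return "d181_360"
    return "d_gt360"


def compute_tto(case: ReportCase, spec: CohortSpec) -> TtoRecord:
    """Days from earliest matched-drug therapy start to event onset.

    Both EVENT_DT and START_DT must parse at day precision; several therapy
    rows for the matched drug use the earliest start.  Absent, partial,
    invalid or negative intervals are ``missing_invalid``.
    """
    event = case.demo.event_dt
    if not event.is_day:
        return TtoRecord(case.primaryid, None, "missing_invalid")
    matched = set(match_drug(case, spec))
    starts = [
        t.start_dt.date
        for t in case.therapies
        if t.dsg_drug_seq in matched and t.start_dt.is_day
    ]
    if not starts:
        return TtoRecord(case.primaryid, None, "missing_invalid")
    days = (event.date - min(starts)).days
    if days < 0:
        return TtoRecord(case.primaryid, None, "missing_invalid")
    return TtoRecord(case.primaryid, days, _bin_tto(days))


def tto_summary(cohort: Sequence[ReportCase], spec: CohortSpec) -> pd.DataFrame:
    """Per-bin TTO counts and percentages, overall and among serious reports.

    ``pct_of_total`` is relative to all cohort reports (the report-table
    convention); ``pct_of_computable`` is among reports with a computable
    TTO.  ``serious_*`` columns repeat both restricted to serious reports.
    """
    overall = {b: 0 for b in TTO_BINS}
    serious = {b: 0 for b in TTO_BINS}
    n_serious = 0
    for case in cohort:
        rec = compute_tto(case, spec)
        overall[rec.bin] += 1
        if classify_serious(case)[0]:
            n_serious += 1
            serious[rec.bin] += 1
    n_total = len(cohort)
    computable = n_total - overall["missing_invalid"]
    serious_computable = n_serious - serious["missing_invalid"]
    rows = []
    for b in TTO_BINS:
        is_missing = b == "missing_invalid"
        rows.append(
            {
                "bin": TTO_BIN_LABELS[b],
                "count": overall[b],
                "pct_of_total": proportion_pct(overall[b], n_total),
                "pct_of_computable": float("nan")
                if is_missing
                else proportion_pct(overall[b], computable),
                "serious_count": serious[b],
                "serious_pct_of_total": proportion_pct(serious[b], n_serious),
                "serious_pct_of_computable": float("nan")
                if is_missing
                else proportion_pct(serious[b], serious_computable),
            }
        )
    return pd.DataFrame(rows)
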