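"""Target-drug cohort extraction and comparator background.

A report enters the cohort when the target drug appears with an allowed role
code (by default primary suspect, PS) under a drug-name synonym match, and —
when an indication filter is configured — the matched drug sequence carries a
qualifying indication.  Everything else is the comparator background, so
cohort and background always partition the deduplicated report set.

The 120 mg oncology dose of denosumab is selected by brand identity (Xgeva
synonyms plus oncology indication terms), not by parsing dose fields: during
the study window Xgeva was the only denosumab product licensed for
cancer-related indications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import yaml

from faerspv.faers_io import ReportCase, normalize_term

EXACT = "exact"
SUBSTRING = "substring"

#: shipped default: denosumab 120 mg (Xgeva) with oncology indications.
#: Best-effort, editable — not an authoritative indication dictionary.
DEFAULT_SYNONYMS = ("denosumab (xgeva)", "xgeva", "denosumab")
DEFAULT_INDICATION_TERMS = (
    "bone metastases",
    "metastases to bone",
    "bone cancer",
    "giant cell tumor of bone",
    "giant cell tumour of bone",
    "multiple myeloma",
    "prostate cancer",
    "breast cancer",
    "neoplasm malignant",
    "skeletal related event",
)


@dataclass(frozen=True)
class CohortSpec:
    """Drug synonyms, allowed role codes, indication terms and match mode."""

    drug_synonyms: Tuple[str, ...] = DEFAULT_SYNONYMS
    role_codes: Tuple[str, ...] = ("PS",)
    indication_terms: Tuple[str, ...] = ()  # empty = no indication filter
    match_mode: str = SUBSTRING
    strict_indications: bool = False  # drop reports lacking INDI rows for the drug

    def __post_init__(self) -> None:
        if not self.drug_synonyms:
            raise ValueError("CohortSpec requires at least one drug synonym")
        if self.match_mode not in (EXACT, SUBSTRING):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            drug_synonyms=tuple(d.get("drug_synonyms", DEFAULT_SYNONYMS)),
            role_codes=tuple(d.get("role_codes", ("PS",))),
            indication_terms=tuple(d.get("indication_terms", ())),
            match_mode=d.get("match_mode", SUBSTRING),
            strict_indications=bool(d.get("strict_indications", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _term_matches(value: str, term: str, mode: str) -> bool:
    value_n = normalize_term(value)
    term_n = normalize_term(term)
    if not value_n or not term_n:
        return False
    return value_n == term_n if mode == EXACT else term_n in value_n


def match_drug(case: ReportCase, spec: CohortSpec) -> List[str]:
    """Drug sequences whose DRUGNAME or PROD_AI matches any synonym."""
    matched = []
    for drug in case.drugs:
        if any(
            _term_matches(drug.drugname, syn, spec.match_mode)
            or _term_matches(drug.prod_ai, syn, spec.match_mode)
            for syn in spec.drug_synonyms
        ):
            matched.append(drug.drug_seq)
    return matched


def in_cohort(case: ReportCase, spec: CohortSpec) -> bool:
    """True iff some matched drug has an allowed role and passes the indication filter.

    When ``indication_terms`` is non-empty, the indications linked to the
    matched drug sequence must contain a qualifying term.  Reports with no
    INDI rows for that sequence are kept unless ``strict_indications`` — FAERS
    reports frequently lack indication rows, and silently discarding them
    would bias the cohort; both behaviours are available.
    """
    matched = set(match_drug(case, spec))
    if not matched:
        return False
    roles = set(spec.role_codes)
    for drug in case.drugs:
        if drug.drug_seq not in matched or drug.role_cod not in roles:
            continue
        if not spec.indication_terms:
            return True
        indications = [i for i in case.indications if i.indi_drug_seq == drug.drug_seq]
        if not indications:
            if not spec.strict_indications:
                return True
            continue
        if any(
            _term_matches(ind.indi_pt, term, spec.match_mode)
            for ind in indications
            for term in spec.indication_terms
        ):
            return True
    return False


def split_background(
    cases: Sequence[ReportCase], spec: CohortSpec
) -> Tuple[List[ReportCase], List[ReportCase]]:
    """Partition deduplicated cases into (cohort, background)."""
    cohort: List[ReportCase] = []
    background: List[ReportCase] = []
    for case in cases:
        (cohort if in_cohort(case, spec) else background).append(case)
    return cohort, background
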