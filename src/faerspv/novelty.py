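"""Screen for new suspected adverse events among strong signals.

The screen keeps signals positive by both methods whose Bayesian grade is at
least a minimum (default moderate, i.e. IC lower bound > 1.5), drops
categories judged irrelevant to drug toxicity (by default the social
circumstances, product issues, and surgical/medical procedures organ
classes, plus explicit terms such as off-label use), and splits the
survivors by presence in the product-label PT list: labeled vs new
suspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import FrozenSet, List, Sequence

from faerspv.faers_io import normalize_term
from faerspv.signal_stats import GRADE_ORDER, Grade, SignalRecord

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_SOCS = frozenset(
    {
        "Social circumstances",
        "Product issues",
        "Surgical and medical procedures",
    }
)

DEFAULT_EXCLUDED_PTS = frozenset(
    {
        "off label use",
        "product use in unapproved indication",
    }
)


@dataclass(frozen=True)
class LabelPtList:
    """Normalized PT names found in the product labeling."""

    labeled_pts: FrozenSet[str]
    source_label: str = ""

    @classmethod
    def from_terms(cls, terms: Sequence[str], source_label: str = "") -> "LabelPtList":
        return cls(
            labeled_pts=frozenset(normalize_term(t) for t in terms if t.strip()),
            source_label=source_label,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelPtList":
        """One PT per line; '#' starts a comment."""
        terms = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.append(line)
        return cls.from_terms(terms, source_label=str(path))

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.labeled_pts


@dataclass(frozen=True)
class ExclusionPolicy:
    """SOCs and PTs removed as clearly unrelated to drug toxicity."""

    excluded_socs: FrozenSet[str] = DEFAULT_EXCLUDED_SOCS
    excluded_pts: FrozenSet[str] = DEFAULT_EXCLUDED_PTS

    def excludes(self, record: SignalRecord) -> bool:
        return record.soc in self.excluded_socs or normalize_term(record.pt) in {
            normalize_term(p) for p in self.excluded_pts
        }


@dataclass
class ScreenResult:
    retained: List[SignalRecord] = field(default_factory=list)
    labeled: List[SignalRecord] = field(default_factory=list)
    new_suspected: List[SignalRecord] = field(default_factory=list)


def screen(
    records: Sequence[SignalRecord],
    label: LabelPtList,
    policy: ExclusionPolicy = ExclusionPolicy(),
    min_grade: Grade | str = Grade.moderate,
    require_ror_grade: bool = False,
) -> ScreenResult:
    """Retain strong both-method signals and split them by label status.

    Retention requires ``positive_both``, a Bayesian grade >= ``min_grade``
    (the screen keys on the IC criterion; set ``require_ror_grade`` to also
    require the ROR grade to reach the cutpoint) and survival of the
    exclusion policy.  Retained = labeled ∪ new_suspected, disjoint.  An
    empty label list flags everything as new, with a prominent warning.
    """
    min_grade = Grade(min_grade)
    floor = GRADE_ORDER[min_grade]
    if not label.labeled_pts:
        logger.warning(
            "empty product-label PT list: every retained signal will be "
            "flagged as new suspected"
        )
    result = ScreenResult()
    for rec in records:
        if not rec.positive_both:
            continue
        if GRADE_ORDER[rec.bcpnn_grade] < floor:
            continue
        if require_ror_grade and GRADE_ORDER[rec.ror_grade] < floor:
            continue
        if policy.excludes(rec):
            continue
        result.retained.append(rec)
        (result.labeled if rec.pt in label else result.new_suspected).append(rec)
    return result


def bundled_label_list() -> LabelPtList:
    """The packaged synthetic label fixture (``data/label_pts_synthetic.txt``).

    A hand-assembled stand-in standing in for real prescribing information,
    shipped so the screen's logic is exercisable end-to-end; real analyses
    must supply the actual product label's PT list.
    """
    ref = resources.files("faerspv").joinpath("data/label_pts_synthetic.txt")
    with resources.as_file(ref) as path:
        return LabelPtList.from_file(path)
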