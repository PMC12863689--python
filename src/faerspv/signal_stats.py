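"""Disproportionality statistics: 2x2 tables, ROR and BCPNN, grading, rankings.

The counting unit is the (deduplicated report, unique PT) pair.  For a PT of
interest the 2x2 table is

    a  = cohort reports mentioning the PT
    b  = remaining cohort units (other PTs)
    c  = background reports mentioning the PT
    d  = remaining background units
    n  = a + b + c + d  (total units in the database)

The reporting odds ratio is ROR = ad/bc with a Woolf log-normal confidence
interval, exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)).  The information
component of the Bayesian confidence propagation neural network (BCPNN) is
IC = log2[ a·n / ((a+b)(a+c)) ]; the default "bayes" mode uses the classic
closed-form posterior expectation and variance with the standard reference
priors (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1, gamma scaled to
the margins), and the 95% band is E(IC) ± 2·sqrt(V(IC)).

Positivity requires a >= 3 with ROR lower bound >= 1 (frequency method) and
IC025 > 0 (Bayesian method); signal strength is graded weak / moderate /
high from the same lower bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from faerspv.faers_io import ReportCase, normalize_term
from faerspv.meddra import PtSocMap, soc_of

LOG2 = math.log(2.0)

RAW = "raw"
BAYES = "bayes"


class Grade(str, Enum):
    none = "none"
    weak = "weak"
    moderate = "moderate"
    high = "high"


GRADE_ORDER = {Grade.none: 0, Grade.weak: 1, Grade.moderate: 2, Grade.high: 3}


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool


@dataclass(frozen=True, slots=True)
class IcResult:
    ic: float
    ic025: float
    ic975: float
    mode: str


@dataclass(frozen=True, slots=True)
class StrengthThresholds:
    """Cutpoints on the lower CI bounds defining weak/moderate/high signals."""

    ror_cuts: Tuple[float, float, float] = (1.0, 50.0, 1000.0)
    ic_cuts: Tuple[float, float, float] = (0.0, 1.5, 3.0)

    def __post_init__(self) -> None:
        for cuts in (self.ror_cuts, self.ic_cuts):
            if not (cuts[0] < cuts[1] < cuts[2]):
                raise ValueError(f"cutpoints must be strictly increasing: {cuts}")


DEFAULT_THRESHOLDS = StrengthThresholds()


@dataclass(slots=True)
class SignalRecord:
    pt: str
    soc: str
    a: int
    ror: RorResult
    ic: IcResult
    positive_ror: bool = False
    positive_bcpnn: bool = False
    positive_both: bool = False
    ror_grade: Grade = Grade.none
    bcpnn_grade: Grade = Grade.none


# ---------------------------------------------------------------------------
# counting


@dataclass
class UnitCounts:
    """Per-PT a/c counts plus the unit totals needed to complete any 2x2 table."""

    a: Dict[str, int]
    c: Dict[str, int]
    cohort_units: int
    background_units: int
    display: Dict[str, str]  # normalized pt -> first-seen spelling

    @property
    def n(self) -> int:
        return self.cohort_units + self.background_units

    def pts(self) -> List[str]:
        keys = set(self.a) | set(self.c)
        return sorted(keys)

    def table_for(self, pt: str) -> ContingencyTable:
        key = normalize_term(pt)
        a = self.a.get(key, 0)
        c = self.c.get(key, 0)
        return ContingencyTable(a=a, b=self.cohort_units - a, c=c, d=self.background_units - c)


def count_units(
    cohort: Sequence[ReportCase], background: Sequence[ReportCase]
) -> UnitCounts:
    """Count (report, unique PT) units in the cohort and background arms."""
    a: Dict[str, int] = {}
    c: Dict[str, int] = {}
    display: Dict[str, str] = {}
    cohort_units = 0
    background_units = 0
    for case in cohort:
        for pt in case.pts:
            key = normalize_term(pt)
            a[key] = a.get(key, 0) + 1
            display.setdefault(key, pt)
            cohort_units += 1
    for case in background:
        for pt in case.pts:
            key = normalize_term(pt)
            c[key] = c.get(key, 0) + 1
            display.setdefault(key, pt)
            background_units += 1
    return UnitCounts(
        a=a, c=c, cohort_units=cohort_units, background_units=background_units, display=display
    )


# ---------------------------------------------------------------------------
# statistics


def compute_ror(t: ContingencyTable, continuity: bool = False) -> RorResult:
    """ROR = ad/bc with the 95% Woolf interval.

    A zero in any cell leaves the ratio or its CI undefined; such tables are
    returned with ``defined=False`` (ror/CI set to nan) unless ``continuity``
    applies the Haldane–Anscombe 0.5 correction to every cell.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if continuity and min(t.a, t.b, t.c, t.d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return RorResult(ror=math.nan, ci_low=math.nan, ci_high=math.nan, defined=False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return RorResult(
        ror=ror,
        ci_low=math.exp(math.log(ror) - 1.96 * se),
        ci_high=math.exp(math.log(ror) + 1.96 * se),
        defined=True,
    )


def _bcpnn_moments(t: ContingencyTable) -> Tuple[float, float]:
    """Closed-form posterior E(IC) and V(IC) with the standard reference priors."""
    a, n = float(t.a), float(t.n)
    a_b = float(t.a + t.b)
    a_c = float(t.a + t.c)
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a_b + alpha1) * (a_c + beta1))
    e_ic = math.log(
        (a + gamma11) * (n + alpha) * (n + beta) / ((n + gamma) * (a_b + alpha1) * (a_c + beta1))
    ) / LOG2
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1.0 + n + gamma))
        + (n - a_b + alpha - alpha1) / ((a_b + alpha1) * (1.0 + n + alpha))
        + (n - a_c + beta - beta1) / ((a_c + beta1) * (1.0 + n + beta))
    ) / (LOG2 ** 2)
    return e_ic, v_ic


def compute_ic(t: ContingencyTable, mode: str = BAYES) -> IcResult:
    """Information component with a 95% band (point ± 2·sqrt(V(IC))).

    ``bayes`` (default): the closed-form posterior expectation E(IC) is the
    point estimate.  ``raw``: the point estimate is the observed
    log2[a·n/((a+b)(a+c))] (nan when a = 0); the band is centred on the raw
    point using the same posterior variance, since the raw statistic carries
    no variance of its own.
    """
    if t.n == 0:
        raise ValueError("compute_ic requires n > 0")
    if mode not in (RAW, BAYES):
        raise ValueError(f"unknown ic mode {mode!r}")
    e_ic, v_ic = _bcpnn_moments(t)
    sd2 = 2.0 * math.sqrt(v_ic)
    if mode == BAYES:
        point = e_ic
    else:
        if t.a == 0 or (t.a + t.b) == 0 or (t.a + t.c) == 0:
            point = math.nan
        else:
            point = math.log(t.a * t.n / ((t.a + t.b) * (t.a + t.c))) / LOG2
    if math.isnan(point):
        return IcResult(ic=math.nan, ic025=math.nan, ic975=math.nan, mode=mode)
    return IcResult(ic=point, ic025=point - sd2, ic975=point + sd2, mode=mode)


def classify_positive(a: int, ror: RorResult, ic: IcResult) -> Tuple[bool, bool, bool]:
    """(positive_ror, positive_bcpnn, positive_both).

    Frequency method: a >= 3, ROR defined and lower 95% bound >= 1.
    Bayesian method: IC025 > 0 (strict).
    """
    positive_ror = a >= 3 and ror.defined and ror.ci_low >= 1.0
    positive_bcpnn = (not math.isnan(ic.ic025)) and ic.ic025 > 0.0
    return positive_ror, positive_bcpnn, positive_ror and positive_bcpnn


def grade_strength(
    ror: RorResult,
    ic: IcResult,
    positive_ror: bool,
    positive_bcpnn: bool,
    thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
) -> Tuple[Grade, Grade]:
    """Grade each method from its lower CI bound; non-positive -> none.

    The boundary conventions differ by method.  ROR bands are closed on the
    left: weak [cut0, cut1), moderate [cut1, cut2), high [cut2, inf), so a
    lower bound of exactly 50 is moderate.  IC bands are closed on the
    right: weak (cut0, cut1], moderate (cut1, cut2], high (cut2, inf), so a
    lower bound of exactly 1.5 is still weak and moderate requires a
    strictly larger value.  Either way the grades partition the positive
    range.
    """
    if positive_ror:
        lo = ror.ci_low
        ror_grade = (
            Grade.weak
            if lo < thresholds.ror_cuts[1]
            else Grade.moderate
            if lo < thresholds.ror_cuts[2]
            else Grade.high
        )
    else:
        ror_grade = Grade.none
    if positive_bcpnn:
        lo = ic.ic025
        bcpnn_grade = (
            Grade.weak
            if lo <= thresholds.ic_cuts[1]
            else Grade.moderate
            if lo <= thresholds.ic_cuts[2]
            else Grade.high
        )
    else:
        bcpnn_grade = Grade.none
    return ror_grade, bcpnn_grade


# ---------------------------------------------------------------------------
# record assembly, rankings, rollups


def build_signal_records(
    counts: UnitCounts,
    pt_soc_map: PtSocMap,
    ic_mode: str = BAYES,
    thresholds: StrengthThresholds = DEFAULT_THRESHOLDS,
    continuity: bool = False,
) -> List[SignalRecord]:
    """One fully evaluated SignalRecord per PT observed in the cohort arm."""
    records: List[SignalRecord] = []
    for key in sorted(counts.a):
        pt = counts.display[key]
        t = counts.table_for(pt)
        ror = compute_ror(t, continuity=continuity)
        ic = compute_ic(t, mode=ic_mode)
        pos_r, pos_b, pos_both = classify_positive(t.a, ror, ic)
        gr, gb = grade_strength(ror, ic, pos_r, pos_b, thresholds)
        records.append(
            SignalRecord(
                pt=pt,
                soc=soc_of(pt, pt_soc_map),
                a=t.a,
                ror=ror,
                ic=ic,
                positive_ror=pos_r,
                positive_bcpnn=pos_b,
                positive_both=pos_both,
                ror_grade=gr,
                bcpnn_grade=gb,
            )
        )
    return records


def concordance(
    ror_positive: Set[str] | Iterable[str], bcpnn_positive: Set[str] | Iterable[str]
) -> Tuple[int, Optional[float]]:
    """Overlap of the two methods' positive PT sets.

    Returns (|intersection|, 100·|intersection|/|ror_positive|); the fraction
    is None when the ROR-positive set is empty.
    """
    ror_set = {normalize_term(p) for p in ror_positive}
    bcpnn_set = {normalize_term(p) for p in bcpnn_positive}
    overlap = len(ror_set & bcpnn_set)
    if not ror_set:
        return overlap, None
    return overlap, 100.0 * overlap / len(ror_set)


def rank_signals(records: Sequence[SignalRecord], by: str = "frequency") -> List[SignalRecord]:
    """Stable descending sort by case count or ROR point estimate.

    Ties (and undefined RORs, which sort last) break alphabetically by PT.
    """
    if by == "frequency":
        keyfn = lambda r: (-r.a, normalize_term(r.pt))
    elif by == "ror":
        keyfn = lambda r: (
            -(r.ror.ror if r.ror.defined else -math.inf),
            normalize_term(r.pt),
        )
    else:
        raise ValueError(f"unknown ranking {by!r}")
    return sorted(records, key=keyfn)


def proportion_pct(count: int, total: int) -> float:
    """count/total as a percentage rounded to 2 decimals (report convention)."""
    if total == 0:
        return math.nan
    return round(100.0 * count / total, 2)


def soc_distribution(positive_records: Sequence[SignalRecord]) -> pd.DataFrame:
    """Distinct positive PTs per SOC with proportions of all positives.

    Returns a DataFrame (soc, n_signals, proportion_pct) sorted by descending
    signal count then SOC name; proportions are percentages to 2 decimals and
    sum to ~100.
    """
    total = len(positive_records)
    counts: Dict[str, int] = {}
    for rec in positive_records:
        counts[rec.soc] = counts.get(rec.soc, 0) + 1
    rows = [
        {"soc": soc, "n_signals": n, "proportion_pct": proportion_pct(n, total)}
        for soc, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["soc", "n_signals", "proportion_pct"])
    return df.sort_values(["n_signals", "soc"], ascending=[False, True]).reset_index(drop=True)


def signals_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    """Flat signals table, statistics rounded to 2 decimals for report output."""
    rows = []
    for r in records:
        rows.append(
            {
                "pt": r.pt,
                "soc": r.soc,
                "a": r.a,
                "ror": round(r.ror.ror, 2) if r.ror.defined else math.nan,
                "ror_ci_low": round(r.ror.ci_low, 2) if r.ror.defined else math.nan,
                "ror_ci_high": round(r.ror.ci_high, 2) if r.ror.defined else math.nan,
                "ic": round(r.ic.ic, 2),
                "ic025": round(r.ic.ic025, 2),
                "positive_ror": r.positive_ror,
                "positive_bcpnn": r.positive_bcpnn,
                "positive_both": r.positive_both,
                "ror_grade": r.ror_grade.value,
                "bcpnn_grade": r.bcpnn_grade.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pt",
            "soc",
            "a",
            "ror",
            "ror_ci_low",
            "ror_ci_high",
            "ic",
            "ic025",
            "positive_ror",
            "positive_bcpnn",
            "positive_both",
            "ror_grade",
            "bcpnn_grade",
        ],
    )
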