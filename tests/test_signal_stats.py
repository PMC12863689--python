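"""Disproportionality statistics against independent arithmetic oracles.

The oracle functions below re-derive ROR, its Woolf interval, and the
closed-form BCPNN posterior moments directly from the defining expressions,
using a different code path (numpy scalars, expanded algebra) from the
implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.dates import parse_date
from faerspv.faers_io import DemoRecord, ReactionRecord, ReportCase
from faerspv.meddra import PtSocMap
from faerspv.signal_stats import (
    ContingencyTable,
    Grade,
    IcResult,
    RorResult,
    StrengthThresholds,
    build_signal_records,
    classify_positive,
    compute_ic,
    compute_ror,
    concordance,
    count_units,
    grade_strength,
    proportion_pct,
    rank_signals,
    soc_distribution,
)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_ror(a, b, c, d):
    odds_ratio = (a / b) / (c / d)
    se = np.sqrt(sum(1.0 / x for x in (a, b, c, d)))
    lo = np.exp(np.log(odds_ratio) - 1.96 * se)
    hi = np.exp(np.log(odds_ratio) + 1.96 * se)
    return float(odds_ratio), float(lo), float(hi)


def oracle_bcpnn(a, b, c, d):
    """Closed-form posterior E(IC), V(IC) with reference priors, re-derived."""
    n = a + b + c + d
    g = (n + 2.0) * (n + 2.0) / ((a + b + 1.0) * (a + c + 1.0))
    e_num = (a + 1.0) * (n + 2.0) * (n + 2.0)
    e_den = (n + g) * (a + b + 1.0) * (a + c + 1.0)
    e_ic = np.log2(e_num / e_den)
    v = (
        (n - a + g - 1.0) / ((a + 1.0) * (1.0 + n + g))
        + (n - a - b + 1.0) / ((a + b + 1.0) * (3.0 + n))
        + (n - a - c + 1.0) / ((a + c + 1.0) * (3.0 + n))
    ) / (np.log(2.0) ** 2)
    return float(e_ic), float(v)


def make_case(pid, pts):
    demo = DemoRecord(
        primaryid=pid, caseid=pid, fda_dt=parse_date("20200101"), event_dt=parse_date("")
    )
    return ReportCase(demo=demo, reactions=[ReactionRecord(pid, p) for p in pts])


# ---------------------------------------------------------------------------
# counting


class TestCountUnits:
    def test_hand_counted_two_report_example(self):
        cohort = [make_case("1", ["X", "Y"])]
        background = [make_case("2", ["X"])]
        counts = count_units(cohort, background)
        t = counts.table_for("X")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_repeated_pt_in_one_report_counts_once(self):
        counts = count_units([make_case("1", ["X", "x "])], [])
        assert counts.table_for("X").a == 1

    def test_empty_background_gives_zero_c_d(self):
        counts = count_units([make_case("1", ["X"])], [])
        t = counts.table_for("X")
        assert (t.c, t.d) == (0, 0)

    def test_per_pt_a_sums_to_cohort_units_and_cells_sum_to_n(self):
        cohort = [make_case("1", ["X", "Y"]), make_case("2", ["Y", "Z"])]
        background = [make_case("3", ["X"]), make_case("4", ["Z", "W"])]
        counts = count_units(cohort, background)
        assert sum(counts.a.values()) == counts.cohort_units == 4
        for pt in counts.pts():
            assert counts.table_for(pt).n == counts.n


# ---------------------------------------------------------------------------
# ROR


class TestRor:
    def test_symmetric_table_is_null(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_frozen_worked_example(self):
        # a=10, b=90, c=100, d=9900: ROR = ad/bc = 11, Woolf interval
        r = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0, rel=1e-12)
        assert r.ci_low == pytest.approx(5.559514928894626, rel=1e-9)
        assert r.ci_high == pytest.approx(21.76448872744693, rel=1e-9)

    def test_zero_cell_is_undefined(self):
        r = compute_ror(ContingencyTable(3, 0, 5, 100))
        assert not r.defined and math.isnan(r.ror)

    def test_haldane_correction_defines_zero_cell_tables(self):
        r = compute_ror(ContingencyTable(3, 0, 5, 100), continuity=True)
        assert r.defined
        assert r.ror == pytest.approx((3.5 * 100.5) / (0.5 * 5.5), rel=1e-12)

    def test_monotone_in_a_with_other_cells_fixed(self):
        rors = [compute_ror(ContingencyTable(a, 50, 60, 7000)).ror for a in (3, 10, 40, 200)]
        assert rors == sorted(rors) and len(set(rors)) == len(rors)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# BCPNN IC


class TestIc:
    def test_raw_ic_zero_at_exact_independence(self):
        # a*n == (a+b)(a+c): 1*100 == 10*10
        r = compute_ic(ContingencyTable(1, 9, 9, 81), mode="raw")
        assert r.ic == pytest.approx(0.0, abs=1e-12)

    def test_raw_ic_frozen_example(self):
        r = compute_ic(ContingencyTable(10, 90, 100, 9900), mode="raw")
        assert r.ic == pytest.approx(math.log2(10 * 10100 / (110 * 100)), rel=1e-12)

    def test_bayes_point_matches_closed_form_oracle(self):
        e, v = oracle_bcpnn(10, 90, 100, 9900)
        r = compute_ic(ContingencyTable(10, 90, 100, 9900), mode="bayes")
        assert r.ic == pytest.approx(e, rel=1e-9)
        assert r.ic025 == pytest.approx(e - 2 * math.sqrt(v), rel=1e-9)
        assert r.ic975 == pytest.approx(e + 2 * math.sqrt(v), rel=1e-9)

    def test_bayes_shrinks_small_count_tables_toward_zero(self):
        t = ContingencyTable(4, 30, 40, 8000)
        raw = compute_ic(t, mode="raw").ic
        bayes = compute_ic(t, mode="bayes").ic
        assert raw > bayes > 0.0

    def test_ic025_below_point_below_ic975(self):
        r = compute_ic(ContingencyTable(50, 500, 600, 90000))
        assert r.ic025 < r.ic < r.ic975

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_ic(ContingencyTable(0, 0, 0, 0))

    def test_raw_mode_zero_a_is_nan(self):
        r = compute_ic(ContingencyTable(0, 10, 10, 100), mode="raw")
        assert math.isnan(r.ic) and math.isnan(r.ic025)


cells = st.integers(min_value=1, max_value=500)


@settings(derandomize=True, max_examples=200)
@given(cells, cells, cells, cells)
def test_ror_and_ic_match_oracles_on_random_tables(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    ror, lo, hi = oracle_ror(a, b, c, d)
    r = compute_ror(t)
    assert r.ror == pytest.approx(ror, rel=1e-9)
    assert r.ci_low == pytest.approx(lo, rel=1e-9)
    assert r.ci_high == pytest.approx(hi, rel=1e-9)
    e, v = oracle_bcpnn(a, b, c, d)
    ic = compute_ic(t, mode="bayes")
    assert ic.ic == pytest.approx(e, rel=1e-9, abs=1e-12)
    assert ic.ic025 == pytest.approx(e - 2 * math.sqrt(v), rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# positivity and grading


def ror_result(lo, point=None, hi=None):
    point = lo * 1.2 if point is None else point
    hi = point * 1.2 if hi is None else hi
    return RorResult(ror=point, ci_low=lo, ci_high=hi, defined=True)


def ic_result(lo, point=None):
    point = lo + 0.2 if point is None else point
    return IcResult(ic=point, ic025=lo, ic975=point + (point - lo), mode="bayes")


class TestPositivity:
    def test_high_count_with_sub_unit_ror_bound_is_not_positive(self):
        # frequency-ranked tables legitimately contain non-signals
        flags = classify_positive(282, ror_result(0.83, 0.93, 1.05), ic_result(-0.27, -0.10))
        assert flags == (False, False, False)

    def test_fewer_than_three_cases_is_not_positive(self):
        assert classify_positive(2, ror_result(5.0), ic_result(1.0))[0] is False

    def test_strong_record_positive_by_both(self):
        flags = classify_positive(3082, ror_result(380.92, 396.57, 412.86), ic_result(8.04, 8.23))
        assert flags == (True, True, True)

    def test_boundary_ror_bound_of_one_counts(self):
        assert classify_positive(3, ror_result(1.0), ic_result(0.5))[0] is True

    def test_boundary_ic025_zero_does_not_count(self):
        assert classify_positive(3, ror_result(2.0), ic_result(0.0))[1] is False


class TestGrading:
    @pytest.mark.parametrize(
        "ror_lo,ic_lo,expected",
        [
            (380.92, 8.04, (Grade.moderate, Grade.high)),  # strong dual signal
            (1.16, 1.16, (Grade.weak, Grade.weak)),
            (50.0, 1.5, (Grade.moderate, Grade.weak)),  # boundary: 50 is moderate, 1.5 weak
            (1000.0, 3.01, (Grade.high, Grade.high)),
        ],
    )
    def test_grade_bands(self, ror_lo, ic_lo, expected):
        grades = grade_strength(ror_result(ror_lo), ic_result(ic_lo), True, True)
        assert grades == expected

    def test_non_positive_records_are_ungraded(self):
        grades = grade_strength(ror_result(0.8), ic_result(-0.2), False, False)
        assert grades == (Grade.none, Grade.none)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            StrengthThresholds(ror_cuts=(50.0, 1.0, 1000.0))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1.0, max_value=5000.0, allow_nan=False),
        st.floats(min_value=1e-6, max_value=8.0, allow_nan=False),
    )
    def test_positive_values_fall_in_exactly_one_grade(self, ror_lo, ic_lo):
        gr, gb = grade_strength(ror_result(ror_lo), ic_result(ic_lo), True, True)
        assert gr in (Grade.weak, Grade.moderate, Grade.high)
        assert gb in (Grade.weak, Grade.moderate, Grade.high)


# ---------------------------------------------------------------------------
# concordance, ranking, SOC rollup


class TestConcordance:
    def test_overlap_fraction_printed_to_one_decimal(self):
        ror_set = {f"pt{i}" for i in range(320)}
        bcpnn_set = {f"pt{i}" for i in range(294)}
        overlap, pct = concordance(ror_set, bcpnn_set)
        assert overlap == 294
        assert round(pct, 1) == 91.9

    def test_identical_sets(self):
        assert concordance({"a", "b"}, {"a", "b"}) == (2, 100.0)

    def test_disjoint_sets(self):
        assert concordance({"a"}, {"b"}) == (0, 0.0)

    def test_empty_ror_set_undefined(self):
        overlap, pct = concordance(set(), {"a"})
        assert overlap == 0 and pct is None


def signal(pt, a, ror_point):
    return type(
        "R",
        (),
        {
            "pt": pt,
            "soc": "S",
            "a": a,
            "ror": RorResult(ror_point, ror_point * 0.8, ror_point * 1.2, True),
        },
    )()


class TestRanking:
    def test_frequency_descending(self):
        ranked = rank_signals([signal("X", 5, 2.0), signal("Y", 7, 1.0)], by="frequency")
        assert [r.pt for r in ranked] == ["Y", "X"]

    def test_ties_break_alphabetically(self):
        ranked = rank_signals([signal("b", 5, 1.0), signal("A", 5, 1.0)], by="frequency")
        assert [r.pt for r in ranked] == ["A", "b"]

    def test_matches_independent_sort_on_ten_signals(self):
        rng = np.random.default_rng(11)
        records = [
            signal(f"pt{i}", int(rng.integers(1, 50)), float(rng.uniform(0.5, 100))) for i in range(10)
        ]
        expected = sorted(records, key=lambda r: (-r.ror.ror, r.pt.lower()))
        assert [r.pt for r in rank_signals(records, by="ror")] == [r.pt for r in expected]


class TestSocDistribution:
    def _records(self, soc_counts):
        records = []
        i = 0
        for soc, k in soc_counts.items():
            for _ in range(k):
                rec = signal(f"pt{i}", 5, 3.0)
                rec.soc = soc
                records.append(rec)
                i += 1
        return records

    def test_proportions_of_total_positives(self):
        df = soc_distribution(self._records({"Musculoskeletal": 39, "Other": 294 - 39}))
        row = df[df.soc == "Musculoskeletal"].iloc[0]
        assert row.n_signals == 39
        assert row.proportion_pct == 13.27

    def test_single_soc_is_total(self):
        df = soc_distribution(self._records({"OnlySoc": 4}))
        assert df.proportion_pct.tolist() == [100.0]

    def test_proportion_pct_helper_rounds_to_two_decimals(self):
        assert proportion_pct(47, 294) == 15.99


def test_build_signal_records_full_small_database():
    mapping = PtSocMap(entries={"x": "SocX", "y": "SocY"})
    cohort = [make_case(str(i), ["X"]) for i in range(20)] + [make_case("c21", ["X", "Y"])]
    background = [make_case(f"b{i}", ["Y"]) for i in range(200)] + [
        make_case(f"bx{i}", ["X"]) for i in range(3)
    ]
    records = build_signal_records(count_units(cohort, background), mapping)
    by_pt = {r.pt: r for r in records}
    assert by_pt["X"].soc == "SocX"
    assert by_pt["X"].a == 21
    assert by_pt["X"].positive_both
    assert by_pt["X"].positive_both == (by_pt["X"].positive_ror and by_pt["X"].positive_bcpnn)
    assert not by_pt["Y"].positive_ror
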