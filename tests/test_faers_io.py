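"""Reading the "$"-delimited quarterly dialect and joining report cases."""

from __future__ import annotations

from pathlib import Path

import pytest

from faerspv.faers_io import (
    ReportCase,
    SchemaError,
    age_in_years,
    cases_to_tables,
    join_cases,
    read_table,
    write_tables,
)
from tests.conftest import write_file


class TestReadTable:
    def test_demo_record_count_and_fields(self, demo_file):
        result = read_table(demo_file, "DEMO")
        assert len(result.records) == 2
        rec = result.records[0]
        assert rec.primaryid == "101"
        assert rec.caseid == "1"
        assert rec.fda_dt.raw == "20230101"
        assert rec.sex == "F"
        assert result.n_malformed == 0

    def test_overflow_fields_keep_first_n_and_count(self, tmp_path):
        # embedded "$" beyond arity: first N fields win, overflow is counted
        path = write_file(
            tmp_path / "REAC.txt",
            ["primaryid$pt", "1$Nausea$stray$tail", "2$Headache"],
        )
        result = read_table(path, "REAC")
        manual = "1$Nausea$stray$tail".split("$")[:2]
        assert [result.records[0].primaryid, result.records[0].pt] == manual
        assert result.records[1].pt == "Headache"
        assert result.n_malformed == 1

    def test_short_line_right_padded(self, tmp_path):
        path = write_file(
            tmp_path / "DEMO.txt",
            ["primaryid$caseid$fda_dt$sex", "9$9$20200101"],
        )
        rec = read_table(path, "DEMO").records[0]
        assert rec.sex == ""

    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = write_file(tmp_path / "OUTC.txt", ["primaryid$outc_cod"])
        result = read_table(path, "OUTC")
        assert result.records == []
        assert result.n_data_lines == 0

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        path = write_file(tmp_path / "DEMO.txt", ["primaryid$fda_dt", "1$20200101"])
        with pytest.raises(SchemaError, match="CASEID"):
            read_table(path, "DEMO")

    def test_extra_columns_preserved_in_side_map(self, tmp_path):
        path = write_file(
            tmp_path / "DEMO.txt",
            ["primaryid$caseid$fda_dt$mfr_sndr", "1$1$20200101$ACME"],
        )
        result = read_table(path, "DEMO")
        assert result.extra_columns == {"MFR_SNDR": ["ACME"]}

    def test_legacy_column_aliases(self, tmp_path):
        path = write_file(
            tmp_path / "DEMO.txt",
            ["isr$case$fda_dt$gndr_cod", "5$5$20100101$F"],
        )
        rec = read_table(path, "DEMO").records[0]
        assert rec.primaryid == "5" and rec.caseid == "5" and rec.sex == "F"


class TestJoinCases:
    def _demo(self, tmp_path, rows):
        return read_table(
            write_file(
                tmp_path / "DEMO.txt", ["primaryid$caseid$fda_dt"] + rows
            ),
            "DEMO",
        ).records

    def test_within_report_pt_dedup(self, tmp_path):
        demos = self._demo(tmp_path, ["p1$c1$20200101"])
        reac = read_table(
            write_file(tmp_path / "REAC.txt", ["primaryid$pt", "p1$PT_A", "p1$PT_A "]),
            "REAC",
        ).records
        result = join_cases({"DEMO": demos, "REAC": reac})
        assert [c.pts for c in result.cases] == [["PT_A"]]

    def test_orphan_child_rows_dropped_and_counted(self, tmp_path):
        demos = self._demo(tmp_path, ["p1$c1$20200101"])
        drug = read_table(
            write_file(
                tmp_path / "DRUG.txt",
                ["primaryid$drug_seq$role_cod$drugname", "p2$1$PS$XGEVA"],
            ),
            "DRUG",
        ).records
        result = join_cases({"DEMO": demos, "DRUG": drug})
        assert result.cases[0].drugs == []
        assert result.orphan_counts["DRUG"] == 1

    def test_duplicate_primaryid_in_demo_is_hard_error(self, tmp_path):
        demos = self._demo(tmp_path, ["p1$c1$20200101", "p1$c2$20200202"])
        with pytest.raises(ValueError, match="duplicate PRIMARYID"):
            join_cases({"DEMO": demos})

    def test_hand_joined_two_case_fixture(self, tmp_path):
        demos = self._demo(tmp_path, ["p1$c1$20200101", "p2$c2$20200303"])
        drug = read_table(
            write_file(
                tmp_path / "DRUG.txt",
                [
                    "primaryid$drug_seq$role_cod$drugname$prod_ai",
                    "p1$1$PS$XGEVA$DENOSUMAB",
                    "p2$1$SS$ASPIRIN$",
                ],
            ),
            "DRUG",
        ).records
        outc = read_table(
            write_file(tmp_path / "OUTC.txt", ["primaryid$outc_cod", "p2$HO"]), "OUTC"
        ).records
        result = join_cases({"DEMO": demos, "DRUG": drug, "OUTC": outc})
        by_id = {c.primaryid: c for c in result.cases}
        assert set(by_id) == {"p1", "p2"}
        assert by_id["p1"].drugs[0].drugname == "XGEVA"
        assert by_id["p1"].outcomes == []
        assert by_id["p2"].drugs[0].role_cod == "SS"
        assert by_id["p2"].outcomes[0].outc_cod == "HO"

    def test_case_count_equals_distinct_demo_primaryids(self, recovery_run):
        demos = recovery_run["tables"]["DEMO"]
        assert len(recovery_run["joined"].cases) == len({d.primaryid for d in demos})


def test_round_trip_preserves_mandatory_fields(tmp_path, demo_file):
    tables = {
        "DEMO": read_table(demo_file, "DEMO").records,
    }
    reac = write_file(
        tmp_path / "REAC24Q1.txt", ["primaryid$pt", "101$Nausea", "201$Pyrexia"]
    )
    tables["REAC"] = read_table(reac, "REAC").records
    cases = join_cases(tables).cases
    out = tmp_path / "rt"
    write_tables(cases_to_tables(cases), out)
    reread = join_cases(
        {
            "DEMO": read_table(out / "DEMOSIM.txt", "DEMO").records,
            "REAC": read_table(out / "REACSIM.txt", "REAC").records,
        }
    ).cases
    orig = {c.primaryid: c for c in cases}
    new = {c.primaryid: c for c in reread}
    assert set(orig) == set(new)
    for pid in orig:
        assert orig[pid].demo.caseid == new[pid].demo.caseid
        assert orig[pid].demo.fda_dt.raw == new[pid].demo.fda_dt.raw
        assert orig[pid].pts == new[pid].pts


@pytest.mark.parametrize(
    "age,cod,expected",
    [
        ("7", "DEC", 70.0),
        ("70", "YR", 70.0),
        ("24", "MON", 2.0),
        ("365.25", "DY", 1.0),
        ("5", "??", None),
        ("", "YR", None),
        ("abc", "YR", None),
    ],
)
def test_age_unit_conversion(age, cod, expected):
    result = age_in_years(age, cod)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)
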