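"""Shared fixtures: handmade mini-tables and one acceptance-scale synthetic run."""

from __future__ import annotations

from pathlib import Path

import pytest

from faerspv.cohort import CohortSpec, split_background
from faerspv.dedup import DedupAudit, deduplicate, restrict_cases
from faerspv.faers_io import join_cases, read_quarter_dir
from faerspv.meddra import bundled_map
from faerspv.signal_stats import build_signal_records, count_units
from faerspv.synthetic import SimConfig, simulate


def write_file(path: Path, lines: list[str]) -> Path:
    path.write_text("\n".join(lines) + "\n", encoding="latin-1")
    return path


@pytest.fixture
def demo_file(tmp_path: Path) -> Path:
    return write_file(
        tmp_path / "DEMO24Q1.txt",
        [
            "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occr_country",
            "101$1$20230101$20221215$64$YR$F$US",
            "201$2$20230202$$7$DEC$M$JP",
        ],
    )


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """One full-scale synthetic run shared by the acceptance-style tests.

    Default study conditions: 200,000 reports, target-drug share 0.5%, one
    injected PT (rate ratio 10 on a 1% baseline), fixed seed.  Returns every
    intermediate the tests need so the pipeline executes exactly once.
    """
    config = SimConfig(seed=1)
    sim_dir = tmp_path_factory.mktemp("recovery_sim")
    simulate(config, sim_dir)
    tables = read_quarter_dir(sim_dir)
    joined = join_cases(tables)
    audit = DedupAudit()
    kept = deduplicate([c.demo for c in joined.cases], audit=audit)
    cases = restrict_cases(joined.cases, kept)
    spec = CohortSpec()
    cohort, background = split_background(cases, spec)
    counts = count_units(cohort, background)
    records = build_signal_records(counts, bundled_map())
    return {
        "config": config,
        "sim_dir": sim_dir,
        "tables": tables,
        "joined": joined,
        "dedup_audit": audit,
        "cases": cases,
        "cohort_spec": spec,
        "cohort": cohort,
        "background": background,
        "counts": counts,
        "records": records,
    }
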