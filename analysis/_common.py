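"""Shared plumbing for the numbered analysis drivers.

Each driver operates on the synthetic database written by 01_simulate.py
(default location results/sim_db) and re-derives the deduplicated,
cohort-split case set from it; the computation itself lives in the package.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from faerspv.cohort import CohortSpec, split_background
from faerspv.dedup import DedupAudit, deduplicate, restrict_cases
from faerspv.faers_io import join_cases, read_quarter_dir

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "results" / "sim_db"
RESULTS = ROOT / "results"


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--sim-dir", type=Path, default=SIM_DIR,
                   help="Synthetic database directory (from 01_simulate.py).")
    p.add_argument("--out", type=Path, default=RESULTS, help="Output directory.")
    return p


def load_cohort(sim_dir: Path):
    """Ingest -> join -> dedup -> cohort split; returns the pieces drivers need."""
    tables = read_quarter_dir(sim_dir)
    joined = join_cases(tables)
    audit = DedupAudit()
    kept = deduplicate([c.demo for c in joined.cases], audit=audit)
    cases = restrict_cases(joined.cases, kept)
    spec = CohortSpec()
    cohort, background = split_background(cases, spec)
    return {
        "tables": tables,
        "audit": audit,
        "cases": cases,
        "spec": spec,
        "cohort": cohort,
        "background": background,
    }
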