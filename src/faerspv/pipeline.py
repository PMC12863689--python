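"""End-to-end orchestration: ingest -> dedup -> cohort -> stats -> screen.

Each stage writes its table under the output directory and appends its
input/output record counts to an audit log (``audit.json``), so the report
flow — raw rows, pooled reports, deduplicated cases, cohort size, signal
counts — is reconstructable from one run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from faerspv import dedup as dedup_mod
from faerspv.cohort import CohortSpec, split_background
from faerspv.descriptives import demographics_table, outcome_summary, tto_summary
from faerspv.faers_io import join_cases, read_quarter_dir
from faerspv.meddra import bundled_map, load_map
from faerspv.novelty import ExclusionPolicy, LabelPtList, bundled_label_list, screen
from faerspv.signal_stats import (
    DEFAULT_THRESHOLDS,
    Grade,
    StrengthThresholds,
    build_signal_records,
    concordance,
    count_units,
    rank_signals,
    signals_frame,
    soc_distribution,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; paths validated before compute."""

    input_dir: Path
    out_dir: Path
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    meddra_map_path: Optional[Path] = None  # None -> bundled synthetic fixture
    label_list_path: Optional[Path] = None  # None -> bundled synthetic fixture
    exclusion_policy: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    thresholds: StrengthThresholds = DEFAULT_THRESHOLDS
    ic_mode: str = "bayes"
    outcome_mode: str = "worst"
    min_grade: Grade = Grade.moderate

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")
        for p in (self.meddra_map_path, self.label_list_path):
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"configured path not found: {p}")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the artifact directory.

    Stage order: ingest -> join -> dedup -> cohort split -> unit counts ->
    signal statistics -> descriptives -> novelty screen.  Failures propagate
    with the stage name prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: Dict[str, object] = {}

    stage = "ingest"
    try:
        tables = read_quarter_dir(config.input_dir)
        audit["raw_rows"] = {k: len(v) for k, v in tables.items()}

        stage = "join"
        joined = join_cases(tables)
        audit["joined_reports"] = len(joined.cases)
        audit["orphan_child_rows"] = joined.orphan_counts

        stage = "dedup"
        dd_audit = dedup_mod.DedupAudit()
        kept = dedup_mod.deduplicate([c.demo for c in joined.cases], audit=dd_audit)
        cases = dedup_mod.restrict_cases(joined.cases, kept)
        audit["dedup"] = {
            "input_reports": dd_audit.n_input,
            "distinct_cases": dd_audit.n_cases,
            "followups_dropped": dd_audit.n_dropped,
        }

        stage = "cohort"
        cohort, background = split_background(cases, config.cohort_spec)
        audit["cohort_reports"] = len(cohort)
        audit["background_reports"] = len(background)

        stage = "count"
        counts = count_units(cohort, background)
        audit["cohort_units"] = counts.cohort_units
        audit["background_units"] = counts.background_units

        stage = "stats"
        mapping = (
            load_map(config.meddra_map_path) if config.meddra_map_path else bundled_map()
        )
        records = build_signal_records(
            counts, mapping, ic_mode=config.ic_mode, thresholds=config.thresholds
        )
        frame = signals_frame(rank_signals(records, by="frequency"))
        _write(frame, out / "signals.tsv")
        ror_pos = {r.pt for r in records if r.positive_ror}
        bcpnn_pos = {r.pt for r in records if r.positive_bcpnn}
        overlap, pct = concordance(ror_pos, bcpnn_pos)
        positives = [r for r in records if r.positive_both]
        audit["signals"] = {
            "pts_evaluated": len(records),
            "positive_ror": len(ror_pos),
            "positive_bcpnn": len(bcpnn_pos),
            "positive_both": len(positives),
            "concordance_overlap": overlap,
            "concordance_pct": pct,
        }
        _write(soc_distribution(positives), out / "soc_distribution.tsv")

        stage = "descriptives"
        _write(demographics_table(cohort), out / "demographics.tsv")
        summary = outcome_summary(cohort, mode=config.outcome_mode)
        _write(
            pd.DataFrame(
                [
                    {"item": "Serious", "count": summary.serious_count},
                    {"item": "Non-serious", "count": summary.non_serious_count},
                ]
                + [
                    {"item": code, "count": n}
                    for code, n in summary.per_outcome.items()
                ]
            ),
            out / "outcomes.tsv",
        )
        _write(tto_summary(cohort, config.cohort_spec), out / "tto.tsv")

        stage = "screen"
        label = (
            LabelPtList.from_file(config.label_list_path)
            if config.label_list_path
            else bundled_label_list()
        )
        result = screen(
            records, label, policy=config.exclusion_policy, min_grade=config.min_grade
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "soc": r.soc,
                        "pt": r.pt,
                        "cases": r.a,
                        "new_suspected": r.pt in [x.pt for x in result.new_suspected],
                    }
                    for r in sorted(
                        result.retained, key=lambda r: (r.soc, -r.a, r.pt)
                    )
                ],
                columns=["soc", "pt", "cases", "new_suspected"],
            ),
            out / "screen.tsv",
        )
        audit["screen"] = {
            "retained": len(result.retained),
            "labeled": len(result.labeled),
            "new_suspected": len(result.new_suspected),
        }
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with (out / "audit.json").open("w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
    return out
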