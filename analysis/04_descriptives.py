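"""Tabulate cohort demographics, seriousness/outcomes and time-to-onset.

Writes results/demographics.tsv, results/outcomes.tsv and results/tto.tsv
and prints each table with the percentage conventions used throughout the
report surfaces (percent of total cohort reports, 2 decimals).
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_cohort, parser  # noqa: E402

from faerspv.descriptives import (  # noqa: E402
    OUTCOME_LABELS,
    demographics_table,
    outcome_summary,
    tto_summary,
)
from faerspv.signal_stats import proportion_pct  # noqa: E402


def main() -> None:
    p = parser(__doc__)
    p.add_argument("--outcome-mode", choices=["worst", "occurrence"], default="worst")
    args = p.parse_args()
    state = load_cohort(args.sim_dir)
    cohort, spec = state["cohort"], state["spec"]
    args.out.mkdir(parents=True, exist_ok=True)

    demo = demographics_table(cohort)
    demo.to_csv(args.out / "demographics.tsv", sep="\t", index=False)
    print(f"cohort: {len(cohort)} reports\n")
    print(demo.to_string(index=False))

    summary = outcome_summary(cohort, mode=args.outcome_mode)
    total = summary.total
    rows = [
        {"item": "Serious", "count": summary.serious_count,
         "pct": proportion_pct(summary.serious_count, total)},
        {"item": "Non-serious", "count": summary.non_serious_count,
         "pct": proportion_pct(summary.non_serious_count, total)},
    ] + [
        {"item": OUTCOME_LABELS[code], "count": n, "pct": proportion_pct(n, total)}
        for code, n in sorted(summary.per_outcome.items(), key=lambda kv: -kv[1])
    ]
    out_df = pd.DataFrame(rows)
    out_df.to_csv(args.out / "outcomes.tsv", sep="\t", index=False)
    print(f"\noutcomes ({summary.mode} mode):")
    print(out_df.to_string(index=False))

    tto = tto_summary(cohort, spec)
    tto.to_csv(args.out / "tto.tsv", sep="\t", index=False)
    print("\ntime-to-onset:")
    print(tto.to_string(index=False))


if __name__ == "__main__":
    main()
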