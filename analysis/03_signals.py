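"""Compute disproportionality statistics and rank the signals.

Writes the full signals table (results/signals.tsv), frequency- and
strength-ranked top lists, and the SOC-level distribution of positive
signals; prints the two-method concordance and the injected-signal recovery.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_cohort, parser  # noqa: E402

from faerspv.meddra import bundled_map  # noqa: E402
from faerspv.signal_stats import (  # noqa: E402
    build_signal_records,
    concordance,
    count_units,
    rank_signals,
    signals_frame,
    soc_distribution,
)


def main() -> None:
    args = parser(__doc__).parse_args()
    state = load_cohort(args.sim_dir)
    counts = count_units(state["cohort"], state["background"])
    records = build_signal_records(counts, bundled_map())
    args.out.mkdir(parents=True, exist_ok=True)

    signals_frame(rank_signals(records, by="frequency")).to_csv(
        args.out / "signals.tsv", sep="\t", index=False
    )
    positives = [r for r in records if r.positive_both]
    signals_frame(rank_signals(positives, by="frequency")[:30]).to_csv(
        args.out / "top_by_frequency.tsv", sep="\t", index=False
    )
    signals_frame(rank_signals(positives, by="ror")[:30]).to_csv(
        args.out / "top_by_strength.tsv", sep="\t", index=False
    )
    soc = soc_distribution(positives)
    soc.to_csv(args.out / "soc_distribution.tsv", sep="\t", index=False)

    ror_pos = {r.pt for r in records if r.positive_ror}
    bcpnn_pos = {r.pt for r in records if r.positive_bcpnn}
    overlap, pct = concordance(ror_pos, bcpnn_pos)
    print(f"{len(records)} PTs evaluated over {counts.n} (report, PT) units")
    print(f"{len(positives)} positive by both methods; "
          f"ROR-positive {len(ror_pos)}, overlap {overlap} "
          f"({pct:.1f}% of ROR positives)" if pct is not None else "no ROR positives")
    print("\npositive signals:")
    print(signals_frame(positives).to_string(index=False))
    print("\nSOC distribution of positive signals:")
    print(soc.to_string(index=False))


if __name__ == "__main__":
    main()
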