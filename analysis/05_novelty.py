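"""Screen the strong signals for events absent from the product label.

Keeps both-method positives graded moderate or stronger on the Bayesian
bound (IC lower bound > 1.5), drops drug-irrelevant categories, and splits
the survivors against the bundled synthetic label list.  Writes
results/screen.tsv.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_cohort, parser  # noqa: E402

from faerspv.meddra import bundled_map  # noqa: E402
from faerspv.novelty import bundled_label_list, screen  # noqa: E402
from faerspv.signal_stats import build_signal_records, count_units  # noqa: E402


def main() -> None:
    args = parser(__doc__).parse_args()
    state = load_cohort(args.sim_dir)
    counts = count_units(state["cohort"], state["background"])
    records = build_signal_records(counts, bundled_map())
    result = screen(records, bundled_label_list())

    new_pts = {r.pt for r in result.new_suspected}
    df = pd.DataFrame(
        [
            {"soc": r.soc, "pt": r.pt, "cases": r.a,
             "bcpnn_grade": r.bcpnn_grade.value, "new_suspected": r.pt in new_pts}
            for r in sorted(result.retained, key=lambda r: (r.soc, -r.a, r.pt))
        ],
        columns=["soc", "pt", "cases", "bcpnn_grade", "new_suspected"],
    )
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "screen.tsv", sep="\t", index=False)
    print(
        f"{len(result.retained)} signals at moderate+ strength after exclusions: "
        f"{len(result.labeled)} labeled, {len(result.new_suspected)} new suspected"
    )
    if not df.empty:
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
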