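"""FDA-style deduplication of pooled DEMO records.

A FAERS case accumulates follow-up reports over time; each follow-up is a new
PRIMARYID under the same CASEID.  The standard rule keeps, within each
CASEID, the report with the most recent FDA_DT, breaking FDA_DT ties by the
largest PRIMARYID.  Deduplication runs on the pooled multi-quarter DEMO set
before any drug filtering, because follow-ups routinely land in later
quarters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from faerspv.faers_io import DemoRecord, ReportCase

logger = logging.getLogger(__name__)


def _primaryid_keys(ids: Sequence[str]) -> List[Tuple]:
    """Comparable keys for PRIMARYIDs within one caseid group.

    Numeric when every id in the group parses as an integer, else
    lexicographic on strings zero-padded to the group's maximum width.
    """
    if all(i.isdigit() for i in ids):
        return [(int(i),) for i in ids]
    width = max(len(i) for i in ids)
    return [(i.zfill(width),) for i in ids]


@dataclass
class DedupAudit:
    n_input: int = 0
    n_cases: int = 0
    n_dropped: int = 0


def deduplicate(demos: Sequence[DemoRecord], audit: DedupAudit | None = None) -> List[DemoRecord]:
    """Keep one DEMO record per CASEID: max FDA_DT, ties by max PRIMARYID.

    FDA_DT values that do not parse are treated as older than every parseable
    date.  Output is sorted by CASEID (numeric where possible) so the result
    is deterministic and independent of input order.
    """
    groups: Dict[str, List[DemoRecord]] = {}
    for rec in demos:
        groups.setdefault(rec.caseid, []).append(rec)
    kept: List[DemoRecord] = []
    for caseid, group in groups.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        pid_keys = _primaryid_keys([r.primaryid for r in group])
        best = max(
            range(len(group)),
            key=lambda i: (group[i].fda_dt.sort_key(), pid_keys[i]),
        )
        kept.append(group[best])
    kept.sort(key=lambda r: (0, int(r.caseid)) if r.caseid.isdigit() else (1, r.caseid))
    if audit is not None:
        audit.n_input = len(demos)
        audit.n_cases = len(kept)
        audit.n_dropped = len(demos) - len(kept)
    logger.info(
        "deduplicate: %d records -> %d cases (%d follow-ups dropped)",
        len(demos),
        len(kept),
        len(demos) - len(kept),
    )
    return kept


def restrict_cases(cases: Sequence[ReportCase], kept_demos: Sequence[DemoRecord]) -> List[ReportCase]:
    """Restrict joined cases to the PRIMARYIDs retained by deduplication."""
    keep = {d.primaryid for d in kept_demos}
    return [c for c in cases if c.primaryid in keep]
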