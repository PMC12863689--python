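"""Preferred Term -> System Organ Class mapping.

MedDRA is licensed and cannot be redistributed, so the package takes the
PT->SOC table as user input (tab-delimited: pt, soc[, version]).  Each PT is
mapped to exactly one primary SOC — no multi-axiality — so SOC-level signal
counts always sum to the number of positive PTs.

A small synthetic fixture map ships with the package
(``data/pt_soc_synthetic.tsv``) covering the terms used by the synthetic
database and the test suite; it is a hand-assembled stand-in, not a MedDRA
extract, and real analyses require a licensed map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict

from faerspv.faers_io import normalize_term

logger = logging.getLogger(__name__)

#: sentinel SOC returned for terms absent from the map
UNMAPPED = "UNMAPPED"


@dataclass
class PtSocMap:
    """Case-insensitive PT -> primary SOC lookup table."""

    entries: Dict[str, str] = field(default_factory=dict)  # normalized pt -> soc
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.entries


class MapConflictError(ValueError):
    """Duplicate PT rows with conflicting SOCs in a mapping file."""


def load_map(path: str | Path) -> PtSocMap:
    """Load a tab-delimited pt, soc[, version] file into a :class:`PtSocMap`.

    Duplicate rows with a consistent SOC collapse to one entry; duplicates
    with conflicting SOCs are a hard error naming every conflicting PT.
    """
    entries: Dict[str, str] = {}
    display: Dict[str, str] = {}
    conflicts = []
    version = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: need at least pt<TAB>soc, got {line!r}")
            pt, soc = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                version = parts[2].strip()
            key = normalize_term(pt)
            if key in entries and entries[key] != soc:
                conflicts.append(f"{display[key]!r}: {entries[key]!r} vs {soc!r}")
            else:
                entries[key] = soc
                display[key] = pt
    if conflicts:
        raise MapConflictError(
            "conflicting SOC assignments for PT(s): " + "; ".join(conflicts)
        )
    return PtSocMap(entries=entries, version_label=version)


def soc_of(pt: str, mapping: PtSocMap) -> str:
    """Primary SOC for a PT, or the UNMAPPED sentinel. Pure and total."""
    return mapping.entries.get(normalize_term(pt), UNMAPPED)


def bundled_map() -> PtSocMap:
    """The packaged synthetic PT->SOC fixture (see module docstring)."""
    ref = resources.files("faerspv").joinpath("data/pt_soc_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_map(path)
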