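"""Bundled crossing records and printed sequence fragments.

The package ships the published mating-compatibility data for the
Moscow-region *P. ostreatus* collection as plain CSV/YAML under
``tetramate/data``:

* ``monmon_vs_reference.csv`` — the 20 natural-isolate testers (five
  panels: M-8, M-9, M-13, M-14, M-17) crossed against the four reference
  testers of collection strain M-38; all compatible.
* ``monmon_natural_testers.csv`` — mutual mon--mon crosses among the
  M-8, M-9 and M-13 panels, transcribed cell-for-cell (unprinted cells
  left blank).
* ``monmon_stated_allplus.csv`` — the M-14/M-17 crosses, reported only
  as "fully compatible with each other and with M-8, M-9 and M-13";
  encoded as all-PLUS blocks.
* ``dimon_vs_reference.csv`` — 12 dikaryotic isolates crossed di--mon
  against the M-38 testers; all compatible.
* ``panels.yaml`` — the tester panels with their published genotypes.

Also bundled: the two printed HD2 homeobox fragments (the conserved
DNA-binding region around the WFXNXR motif) of strains PC15 and PC9,
with the printed 1-based start residue of each fragment.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .mating import parse_genotype
from .tables import CrossTable, PanelSpec, RowKind, parse_cross_table

__all__ = [
    "load_monmon_vs_reference",
    "load_natural_crosses",
    "load_stated_crosses",
    "load_dimon_crosses",
    "load_panels",
    "natural_tester_ids",
    "HD2_HOMEOBOX_FRAGMENTS",
    "WFXNXR",
    "HNPYPTS",
]

#: Printed homeobox fragments of the class HD2 proteins, keyed by strain:
#: (fragment sequence, 1-based residue at which the fragment starts).
HD2_HOMEOBOX_FRAGMENTS: Mapping[str, tuple[str, int]] = {
    "PC15": ("MARKSMMTDRQIEVWFQNHRNSR", 179),
    "PC9": ("MARKSMMTERQIEVWFQNHRNRAR", 177),
}

#: Conserved DNA-binding motif of the homeodomain third alpha-helix.
WFXNXR = "WFXNXR"

#: Conserved motif found in class HD1 proteins only ("HNPYPT/S").
HNPYPTS = "HNPYP[TS]"


def _read(name: str) -> str:
    return (resources.files("tetramate") / "data" / name).read_text(encoding="utf-8")


def load_monmon_vs_reference() -> CrossTable:
    """Natural-isolate testers x M-38 reference testers (mon--mon)."""
    return parse_cross_table(_read("monmon_vs_reference.csv"))


def load_natural_crosses() -> CrossTable:
    """Mutual mon--mon crosses among the M-8/M-9/M-13 tester panels."""
    return parse_cross_table(_read("monmon_natural_testers.csv"))


def load_stated_crosses() -> CrossTable:
    """All-PLUS encoding of the stated M-14/M-17 compatibilities."""
    return parse_cross_table(_read("monmon_stated_allplus.csv"))


def load_dimon_crosses() -> CrossTable:
    """Dikaryotic isolates x M-38 testers (di--mon, Buller phenomenon)."""
    return parse_cross_table(_read("dimon_vs_reference.csv"),
                             row_kinds=RowKind.DIKARYON)


def load_panels(include_reference: bool = True) -> list[PanelSpec]:
    """Tester panels (with published genotypes) from the sidecar YAML."""
    doc = yaml.safe_load(_read("panels.yaml"))
    panels = []
    for entry in doc["panels"]:
        if not include_reference and entry["isolate"] == doc.get("reference"):
            continue
        genos = entry.get("genotypes")
        panels.append(PanelSpec(
            isolate=entry["isolate"],
            testers=list(entry["testers"]),
            genotypes=[parse_genotype(g) for g in genos] if genos else None,
        ))
    return panels


def natural_tester_ids() -> list[str]:
    """The 20 monobasidiospore testers of the five natural isolates."""
    return [f"{iso}.m{i}" for iso in ("M-8", "M-9", "M-13", "M-14", "M-17")
            for i in range(1, 5)]
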