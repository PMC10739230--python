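"""Sequence analyses of the matA homeodomain proteins (HD1/HD2).

The matA locus encodes two classes of homeodomain transcription factors.
Both carry the conserved DNA-binding motif WFXNXR in the third alpha-helix
of the homeodomain; HD1 proteins additionally carry the HNPYPT/S motif and
are typically 40--50 residues longer than their HD2 partners.  As
transcription factors they are globular (no transmembrane segment on a
Kyte--Doolittle hydropathy profile) and nuclear, with candidate nuclear
localization signals recognizable as K/R- or P/H-enriched windows.

This module provides the corresponding primitives: a wildcard motif
scanner, windowed Kyte--Doolittle hydropathy with a transmembrane/globular
call, the NLS composition screen, HD1-vs-HD2 length comparison, and a
data model of the matA gene cassette with GFF3 export.

All residue coordinates are 1-based inclusive, following the convention
of protein sequence reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "KYTE_DOOLITTLE",
    "MotifPattern",
    "MotifHit",
    "HydropathyProfile",
    "GlobularityCall",
    "NlsCandidate",
    "LengthComparison",
    "Gene",
    "LocusModel",
    "motif_scan",
    "kd_profile",
    "call_globular",
    "nls_screen",
    "compare_lengths",
    "write_locus_gff",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Hydropathy scale of Kyte & Doolittle (kcal/mol-derived index; positive
#: = hydrophobic).  The canonical per-residue values of the original scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")
    return seq


# ---------------------------------------------------------------------------
# motif scanning

@dataclass(frozen=True)
class MotifPattern:
    """A linear motif over the 20-aa alphabet with X wildcards and [..] sets.

    Examples: ``WFXNXR`` (X = any residue), ``HNPYP[TS]`` (T or S).
    """

    pattern: str
    tokens: tuple[frozenset, ...] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        toks: list[frozenset] = []
        i, p = 0, self.pattern.upper()
        if not p:
            raise ValueError("empty motif pattern")
        while i < len(p):
            ch = p[i]
            if ch == "X":
                toks.append(frozenset(AMINO_ACIDS))
                i += 1
            elif ch == "[":
                j = p.find("]", i)
                if j < 0:
                    raise ValueError(f"unclosed '[' in pattern {self.pattern!r}")
                alts = p[i + 1:j]
                if not alts or any(a not in AMINO_ACIDS for a in alts):
                    raise ValueError(f"invalid alternative set in {self.pattern!r}")
                toks.append(frozenset(alts))
                i = j + 1
            elif ch in AMINO_ACIDS:
                toks.append(frozenset(ch))
                i += 1
            else:
                raise ValueError(f"invalid symbol {ch!r} in pattern {self.pattern!r}")
        object.__setattr__(self, "tokens", tuple(toks))

    def __len__(self) -> int:
        return len(self.tokens)

    def to_regex(self) -> str:
        parts = []
        for tok in self.tokens:
            if len(tok) == len(AMINO_ACIDS):
                parts.append(".")
            elif len(tok) == 1:
                parts.append(next(iter(tok)))
            else:
                parts.append("[" + "".join(sorted(tok)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


def motif_scan(seq: str, pattern: MotifPattern | str,
               sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, ascending by start.

    Case-insensitive; raises on invalid residue symbols, naming the
    position.  Implemented with an overlap-tolerant lookahead regex.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    seq = _validate_sequence(seq)
    rx = re.compile(f"(?=({pattern.to_regex()}))")
    return [MotifHit(sequence_id, m.start() + 1, m.group(1))
            for m in rx.finditer(seq)]


# ---------------------------------------------------------------------------
# hydropathy

@dataclass
class HydropathyProfile:
    """Windowed mean Kyte--Doolittle hydropathy along a sequence.

    ``values[k]`` is the mean over the window centred on residue
    ``centers[k]`` (1-based); profile length = len(seq) - window + 1.
    """

    sequence_id: str
    window: int
    values: np.ndarray
    scale: dict[str, float]

    @property
    def centers(self) -> np.ndarray:
        half = self.window // 2
        return np.arange(len(self.values)) + half + 1


def kd_profile(seq: str, window: int = 19, sequence_id: str = "",
               scale: Optional[dict[str, float]] = None) -> HydropathyProfile:
    """Sliding arithmetic-mean hydropathy profile (window must be odd)."""
    scale = KYTE_DOOLITTLE if scale is None else scale
    seq = _validate_sequence(seq)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    vals = np.array([scale[ch] for ch in seq], dtype=float)
    kernel = np.full(window, 1.0 / window)
    means = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(sequence_id, window, means, dict(scale))


@dataclass
class GlobularityCall:
    """Transmembrane-segment call from a hydropathy profile.

    ``regions`` are maximal runs of window centres whose mean hydropathy
    exceeds the threshold, as 1-based (start, end) centre positions.  A
    protein with no such run is called globular -- the expected outcome for
    a transcription factor.
    """

    globular: bool
    threshold: float
    regions: list[tuple[int, int]]


def call_globular(profile: HydropathyProfile,
                  tm_threshold: float = 1.6) -> GlobularityCall:
    """Call a protein globular unless a sustained hydrophobic run exists.

    The default cutoff 1.6 is the conventional Kyte--Doolittle
    transmembrane threshold for a 19-residue window.
    """
    if profile.window < 7:
        raise ValueError("transmembrane calling needs a window of at least 7")
    above = profile.values > tm_threshold
    centers = profile.centers
    regions: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((int(centers[start]), int(centers[i - 1])))
            start = None
    if start is not None:
        regions.append((int(centers[start]), int(centers[len(above) - 1])))
    return GlobularityCall(globular=not regions, threshold=tm_threshold,
                           regions=regions)


# ---------------------------------------------------------------------------
# NLS composition screen

@dataclass(frozen=True)
class NlsCandidate:
    """A candidate nuclear localization site: a K/R- or P/H-enriched span."""

    sequence_id: str
    nls_class: str  # "basic" (K/R) or "PH" (P/H)
    start: int      # 1-based
    end: int
    max_fraction: float


_NLS_CLASSES = {"basic": set("KR"), "PH": set("PH")}


def nls_screen(seq: str, window: int = 7, min_fraction: float = 4 / 7,
               sequence_id: str = "") -> list[NlsCandidate]:
    """Composition screen for candidate NLS sites.

    Reports every window whose K+R (or P+H) fraction reaches
    ``min_fraction``; overlapping or adjacent windows of the same class
    are merged into one candidate span.  A heuristic composition screen
    only -- no positional model or classifier.
    """
    if window < 4:
        raise ValueError("NLS screening window must be at least 4")
    seq = _validate_sequence(seq)
    out: list[NlsCandidate] = []
    for cls, residues in _NLS_CLASSES.items():
        hits: list[tuple[int, float]] = []
        for s in range(len(seq) - window + 1):
            frac = sum(ch in residues for ch in seq[s:s + window]) / window
            if frac >= min_fraction:
                hits.append((s + 1, frac))
        merged: list[list] = []
        for s, frac in hits:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = s + window - 1
                merged[-1][2] = max(merged[-1][2], frac)
            else:
                merged.append([s, s + window - 1, frac])
        out.extend(NlsCandidate(sequence_id, cls, s, e, f) for s, e, f in merged)
    return sorted(out, key=lambda c: (c.start, c.nls_class))


# ---------------------------------------------------------------------------
# HD1 vs HD2 length comparison

@dataclass
class LengthComparison:
    """Descriptive HD1-minus-HD2 length differences (no thresholding)."""

    mean_difference: float
    min_difference: float
    max_difference: float
    per_pair: Optional[list[int]]  # set when the two sets pair up 1:1


def compare_lengths(hd1_seqs: Sequence[str],
                    hd2_seqs: Sequence[str]) -> LengthComparison:
    """Compare HD1 and HD2 sequence lengths (HD1 minus HD2).

    When the sets have equal size they are compared pairwise in order;
    otherwise the comparison is between set means.
    """
    if not hd1_seqs or not hd2_seqs:
        raise ValueError("both sequence sets must be non-empty")
    l1 = [len(s) for s in hd1_seqs]
    l2 = [len(s) for s in hd2_seqs]
    if len(l1) == len(l2):
        diffs = [a - b for a, b in zip(l1, l2)]
        return LengthComparison(float(np.mean(diffs)), float(min(diffs)),
                                float(max(diffs)), diffs)
    d = float(np.mean(l1) - np.mean(l2))
    return LengthComparison(d, d, d, None)


# ---------------------------------------------------------------------------
# matA locus cassette model

_HD_GENES = {"hd1", "hd1.1", "hd1.2", "hd2"}


@dataclass(frozen=True)
class Gene:
    name: str    # mip | hd1 | hd1.1 | hd1.2 | hd2 | fg
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.name not in _HD_GENES | {"mip", "fg"}:
            raise ValueError(f"unknown gene {self.name!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class LocusModel:
    """Gene order and orientation of one strain's matA cassette.

    The highly variable hd genes (1--3 copies) sit between the conserved
    flanking genes *mip* (mitochondrial intermediate peptidase) and *fg*
    (beta-flanking protein).  When two hd1 copies are present (hd1.1 and
    hd1.2) they are transcribed divergently (opposite strands).  Only gene
    order and orientation are modelled; the published diagrams give no
    base-pair coordinates.
    """

    strain: str
    genes: list[Gene]

    def validate(self) -> list[str]:
        problems: list[str] = []
        names = [g.name for g in self.genes]
        if not names or names[0] != "mip":
            problems.append("locus must start with the mip flanking gene")
        if not names or names[-1] != "fg":
            problems.append("locus must end with the fg flanking gene")
        hd = [n for n in names if n in _HD_GENES]
        if not 1 <= len(hd) <= 3:
            problems.append(f"expected 1-3 hd genes between the flanks, found {len(hd)}")
        if len(set(names)) != len(names):
            problems.append("duplicate gene names")
        extra = [n for n in names[1:-1] if n not in _HD_GENES]
        if extra:
            problems.append(f"non-hd genes inside the cassette: {extra}")
        if "hd1.1" in names and "hd1.2" in names:
            s1 = self.genes[names.index("hd1.1")].strand
            s2 = self.genes[names.index("hd1.2")].strand
            if s1 == s2:
                problems.append("hd1.1 and hd1.2 must be divergently oriented")
        return problems


def write_locus_gff(model: LocusModel, gene_span: int = 1000,
                    spacer: int = 500) -> str:
    """Render a locus model as a GFF3 document on a placeholder scaffold.

    Coordinates are ordinal placeholders (genes laid out left to right
    with fixed spans), encoding order and orientation only.  Raises with
    all validation problems listed if the model violates the cassette
    invariants.
    """
    problems = model.validate()
    if problems:
        raise ValueError("invalid matA locus model: " + "; ".join(problems))
    scaffold = f"{model.strain}_matA_locus"
    lines = ["##gff-version 3"]
    pos = 1
    for g in model.genes:
        start, end = pos, pos + gene_span - 1
        attrs = f"ID=gene:{model.strain}.{g.name};Name={g.name}"
        lines.append("\t".join([scaffold, "tetramate", "gene", str(start),
                                str(end), ".", g.strand, ".", attrs]))
        pos = end + spacer + 1
    return "\n".join(lines) + "\n"
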