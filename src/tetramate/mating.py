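"""Core domain types and compatibility predicates of the tetrapolar mating system.

In tetrapolar basidiomycetes such as *Pleurotus ostreatus*, sexual
compatibility is controlled by two unlinked multiallelic loci, *matA*
(homeodomain transcription factors) and *matB* (pheromones/receptors).
Two haploid monokaryons form a fertile dikaryon only when they carry
different alleles at *both* loci; the dikaryon is diagnosed by clamp
connections on the mycelium.  A dikaryon can in turn dikaryotize a
compatible monokaryon (di--mon cross, the Buller phenomenon) whenever at
least one of its two nuclei is compatible with it.

Everything here is deterministic set algebra over allele labels; the
stochastic simulation of populations lives in :mod:`tetramate.simulate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable

__all__ = [
    "AlleleLabel",
    "MatingGenotype",
    "Dikaryon",
    "InvalidDikaryonError",
    "compatible",
    "dimon_compatible",
    "spore_types",
    "parse_genotype",
    "natural_sort_key",
]

_GENOTYPE_RE = re.compile(r"^A(?P<a>.+?)B(?P<b>.+)$")


class InvalidDikaryonError(ValueError):
    """Raised when two nuclei are not heteroallelic at both mating loci."""


def natural_sort_key(label: str) -> tuple:
    """Sort key treating embedded integers numerically ("A2" < "A10")."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", label)
        if part != ""
    )


@dataclass(frozen=True)
class AlleleLabel:
    """One allele of a mating-type locus.

    Labels are identity-only tokens: two alleles are the same iff their
    (locus, id) pairs are equal; no order semantics beyond display sort.
    """

    locus: str  # "A" or "B"
    id: str     # opaque token, e.g. "A3"

    def __post_init__(self) -> None:
        if self.locus not in ("A", "B"):
            raise ValueError(f"locus must be 'A' or 'B', got {self.locus!r}")
        if not self.id:
            raise ValueError("allele id must be non-empty")

    def __str__(self) -> str:
        return self.id

    def sort_key(self) -> tuple:
        return natural_sort_key(self.id)


@dataclass(frozen=True)
class MatingGenotype:
    """The mating type of one haploid nucleus: one allele at each locus."""

    a: AlleleLabel
    b: AlleleLabel

    def __post_init__(self) -> None:
        if self.a.locus != "A":
            raise ValueError(f"first allele must be at locus A, got {self.a.locus}")
        if self.b.locus != "B":
            raise ValueError(f"second allele must be at locus B, got {self.b.locus}")

    def __str__(self) -> str:
        return f"{self.a.id}{self.b.id}"

    @classmethod
    def from_string(cls, text: str) -> "MatingGenotype":
        return parse_genotype(text)


def parse_genotype(text: str) -> MatingGenotype:
    """Parse the conventional genotype syntax ``A<i>B<j>`` (e.g. "A3B4")."""
    m = _GENOTYPE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse mating genotype {text!r}; expected 'A<i>B<j>'")
    return MatingGenotype(
        a=AlleleLabel("A", "A" + m.group("a")),
        b=AlleleLabel("B", "B" + m.group("b")),
    )


@dataclass(frozen=True)
class Dikaryon:
    """An unordered pair of nuclei heteroallelic at both mating loci.

    Swap-invariant: ``Dikaryon(x, y) == Dikaryon(y, x)``.
    """

    n1: MatingGenotype
    n2: MatingGenotype

    def __post_init__(self) -> None:
        if self.n1.a == self.n2.a or self.n1.b == self.n2.b:
            raise InvalidDikaryonError(
                f"nuclei {self.n1} and {self.n2} are not heteroallelic at both "
                "mating loci; no clamped dikaryon can carry them"
            )

    @property
    def nuclei(self) -> FrozenSet[MatingGenotype]:
        return frozenset((self.n1, self.n2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dikaryon):
            return NotImplemented
        return self.nuclei == other.nuclei

    def __hash__(self) -> int:
        return hash(self.nuclei)

    def __str__(self) -> str:
        a, b = sorted((str(self.n1), str(self.n2)), key=natural_sort_key)
        return f"{a}+{b}"


def compatible(m1: MatingGenotype, m2: MatingGenotype) -> bool:
    """Mon--mon compatibility: heteroallelic at both loci.

    Symmetric and irreflexive; a self-cross is defined (always False)
    rather than an error, matching the "-" diagonal convention of
    published crossing tables.
    """
    return m1.a != m2.a and m1.b != m2.b


def dimon_compatible(d: Dikaryon, m: MatingGenotype) -> bool:
    """Di--mon compatibility (Buller phenomenon).

    The monokaryon is dikaryotized iff it is compatible with at least one
    of the dikaryon's nuclei; invariant under swapping the nuclei.
    """
    return compatible(d.n1, m) or compatible(d.n2, m)


def spore_types(d: Dikaryon) -> FrozenSet[MatingGenotype]:
    """The four meiotic mating types of a dikaryon AxBx + AyBy.

    The two loci are unlinked, so meiosis releases all four combinations
    {AxBx, AxBy, AyBx, AyBy} -- the standard four-tester panel recovered
    from monobasidiospore isolates.  Deterministic (every type returned
    once); per-spore stochastic sampling belongs to the simulator.
    """
    return frozenset(
        MatingGenotype(a=a, b=b)
        for a in (d.n1.a, d.n2.a)
        for b in (d.n1.b, d.n2.b)
    )


def sorted_genotypes(genos: Iterable[MatingGenotype]) -> list[MatingGenotype]:
    """Canonical display order: natural sort on A then B allele ids."""
    return sorted(genos, key=lambda g: (g.a.sort_key(), g.b.sort_key()))
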