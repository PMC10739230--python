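"""Synthetic populations, crossing matrices, and homeodomain-like proteins.

The generator mirrors the field study design: dikaryotic isolates are
drawn from allele pools at the two unlinked mating loci, four-tester
panels are derived from each isolate by meiosis, and mon--mon / di--mon
crossing matrices are predicted from the compatibility rules (optionally
corrupted by symmetric scoring error).  Protein generation emulates the
reported structure of the matA homeodomain proteins: hydrophilic globular
composition, a single embedded WFXNXR DNA-binding motif inside the
class-specific residue window, the HD1-only HNPYPT/S motif, and HD1
sequences 40--50 residues longer than HD2.

Defaults follow the reported biology of *P. ostreatus*: allele pools of
24 matA / 21 matB alleles, 17 isolates, error-free clamp scoring.

All randomness flows through one ``numpy`` generator seeded from the
mandatory config seed, so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mating import AlleleLabel, Dikaryon, MatingGenotype
from .proteins import (AMINO_ACIDS, KYTE_DOOLITTLE, call_globular, kd_profile,
                       motif_scan)
from .tables import Cell, CrossTable, PanelSpec, predict_table

__all__ = [
    "PopulationConfig",
    "SimulatedPopulation",
    "SyntheticProteinConfig",
    "SyntheticProtein",
    "simulate_population",
    "generate_hd_protein",
    "generate_hd_pair",
    "generate_allele_series",
]


# ---------------------------------------------------------------------------
# populations and crossing matrices

@dataclass
class PopulationConfig:
    """Study-design parameters for a simulated mating population.

    ``n_a_pool``/``n_b_pool`` default to the allele richness reported for
    the species (24 matA / 21 matB); ``n_isolates`` to the 17 collected
    dikaryons.  ``error_rate`` is the per-cell symmetric flip probability
    of the +/- scoring (default 0: clamp scoring treated as reliable).
    """

    n_a_pool: int = 24
    n_b_pool: int = 21
    n_isolates: int = 17
    frequency_scheme: str = "uniform"  # "uniform" | "dirichlet"
    dirichlet_concentration: float = 1.0
    error_rate: float = 0.0
    seed: Optional[int] = None
    include_dimon: bool = False

    def __post_init__(self) -> None:
        if self.n_a_pool < 2 or self.n_b_pool < 2:
            raise ValueError("allele pools need at least 2 alleles per locus "
                             "to form heteroallelic dikaryons")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.frequency_scheme not in ("uniform", "dirichlet"):
            raise ValueError(f"unknown frequency scheme {self.frequency_scheme!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SimulatedPopulation:
    """Simulation output plus the ground truth needed to score inference."""

    config: PopulationConfig
    isolates: dict[str, Dikaryon]
    panels: list[PanelSpec]
    testers: dict[str, MatingGenotype]
    monmon: CrossTable
    monmon_noiseless: CrossTable
    dimon: Optional[CrossTable]

    @property
    def n_a_true(self) -> int:
        return len({g.a for g in self.testers.values()})

    @property
    def n_b_true(self) -> int:
        return len({g.b for g in self.testers.values()})


def _frequencies(cfg: PopulationConfig, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    if cfg.frequency_scheme == "uniform":
        return np.full(size, 1.0 / size)
    return rng.dirichlet(np.full(size, cfg.dirichlet_concentration))


def simulate_population(cfg: PopulationConfig) -> SimulatedPopulation:
    """Draw isolates, derive tester panels, and predict crossing tables.

    Each dikaryon is drawn by rejection until heteroallelic at both loci;
    panels are the four meiotic mating types in conventional order; the
    mon--mon table is the full pairwise matrix over all testers.  With
    ``include_dimon``, the isolates are also crossed di--mon against the
    first isolate's panel.  Scoring error flips off-diagonal cells
    independently (a self-cross can never show clamps, so the diagonal is
    left untouched).
    """
    rng = np.random.default_rng(cfg.seed)
    freq_a = _frequencies(cfg, cfg.n_a_pool, rng)
    freq_b = _frequencies(cfg, cfg.n_b_pool, rng)
    pool_a = [AlleleLabel("A", f"A{i + 1}") for i in range(cfg.n_a_pool)]
    pool_b = [AlleleLabel("B", f"B{i + 1}") for i in range(cfg.n_b_pool)]

    isolates: dict[str, Dikaryon] = {}
    panels: list[PanelSpec] = []
    testers: dict[str, MatingGenotype] = {}
    for k in range(cfg.n_isolates):
        name = f"S{k + 1}"
        while True:
            a1, a2 = rng.choice(cfg.n_a_pool, size=2, p=freq_a)
            b1, b2 = rng.choice(cfg.n_b_pool, size=2, p=freq_b)
            if a1 != a2 and b1 != b2:
                break
        n1 = MatingGenotype(pool_a[a1], pool_b[b1])
        n2 = MatingGenotype(pool_a[a2], pool_b[b2])
        isolates[name] = Dikaryon(n1, n2)
        panel_genos = [MatingGenotype(a, b)
                       for a in (n1.a, n2.a) for b in (n1.b, n2.b)]
        ids = [f"{name}.m{i + 1}" for i in range(4)]
        panels.append(PanelSpec(isolate=name, testers=ids, genotypes=panel_genos))
        testers.update(dict(zip(ids, panel_genos)))

    clean = predict_table(testers, testers)
    noisy = CrossTable(
        row_labels=list(clean.row_labels),
        col_labels=list(clean.col_labels),
        entries=[row.copy() for row in clean.entries],
        row_kinds=list(clean.row_kinds),
    )
    if cfg.error_rate > 0:
        flip = {Cell.PLUS: Cell.MINUS, Cell.MINUS: Cell.PLUS}
        for i, r in enumerate(noisy.row_labels):
            for j, c in enumerate(noisy.col_labels):
                if r != c and rng.random() < cfg.error_rate:
                    noisy.entries[i][j] = flip[noisy.entries[i][j]]

    dimon = None
    if cfg.include_dimon:
        ref = panels[0]
        ref_genos = dict(zip(ref.testers, ref.genotypes))
        dimon = predict_table(dict(isolates), ref_genos)

    return SimulatedPopulation(cfg, isolates, panels, testers,
                               monmon=noisy, monmon_noiseless=clean, dimon=dimon)


# ---------------------------------------------------------------------------
# homeodomain-like proteins

#: Species-specific residue windows of the WFXNXR motif start, per class.
MOTIF_WINDOWS = {"HD1": (125, 175), "HD2": (145, 200)}


@dataclass
class SyntheticProteinConfig:
    """Structure parameters for one homeodomain-like protein draw.

    ``hd2_length_range`` sets the HD2 backbone length; HD1 partners are
    longer by a draw from ``hd1_extra_range`` (the reported 40--50 aa).
    ``motif_window`` defaults to the class-specific WFXNXR position window
    (HD1: 125--175; HD2: 145--200, 1-based start residue).
    ``n_term_variability`` is the per-residue resampling rate used when
    deriving allelic variants of the (dimerization) N-terminus.
    """

    hd_class: str = "HD2"
    hd2_length_range: tuple[int, int] = (230, 280)
    hd1_extra_range: tuple[int, int] = (40, 50)
    motif_window: Optional[tuple[int, int]] = None
    n_term_length: int = 60
    n_term_variability: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hd_class not in ("HD1", "HD2"):
            raise ValueError("hd_class must be 'HD1' or 'HD2'")
        if self.motif_window is None:
            self.motif_window = MOTIF_WINDOWS[self.hd_class]
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not 0.0 <= self.n_term_variability <= 1.0:
            raise ValueError("n_term_variability must lie in [0, 1]")


@dataclass
class SyntheticProtein:
    """A generated sequence with its ground-truth annotation."""

    sequence: str
    hd_class: str
    motif_start: int  # 1-based start of the WFXNXR instance
    hnpypts_start: Optional[int] = None  # HD1 only

    @property
    def length(self) -> int:
        return len(self.sequence)


# Background residue distribution biased toward hydrophilic residues
# (weights decay exponentially with Kyte-Doolittle hydropathy), so that
# sustained hydrophobic windows are rare; a rejection step against the
# transmembrane detector then guarantees the globular call outright.
_BG_RESIDUES = list(AMINO_ACIDS)
_BG_WEIGHTS = np.exp(np.array([-0.6 * KYTE_DOOLITTLE[a] for a in _BG_RESIDUES]))
_BG_WEIGHTS /= _BG_WEIGHTS.sum()
_HYDROPHILIC = [a for a in AMINO_ACIDS if KYTE_DOOLITTLE[a] < 0]

_WFXNXR = "WFXNXR"
_HNPYPTS = "HNPYP[TS]"


def _random_residues(n: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(_BG_RESIDUES, size=n, p=_BG_WEIGHTS))


def _instantiate_motif(rng: np.random.Generator) -> str:
    x1, x2 = rng.choice(_HYDROPHILIC, size=2)
    return f"WF{x1}N{x2}R"


def _draw_sequence(length: int, motif_window: tuple[int, int],
                   with_hnpypts: bool, rng: np.random.Generator,
                   max_attempts: int = 200) -> SyntheticProtein | None:
    lo, hi = motif_window
    hi = min(hi, length - len(_WFXNXR) + 1)
    if lo > hi:
        raise ValueError(f"motif window {motif_window} does not fit a "
                         f"sequence of length {length}")
    for _ in range(max_attempts):
        residues = _random_residues(length, rng)
        motif_start = int(rng.integers(lo, hi + 1))  # 1-based
        motif = _instantiate_motif(rng)
        residues[motif_start - 1:motif_start - 1 + len(motif)] = list(motif)
        hn_start = None
        if with_hnpypts:
            hn_start = int(rng.integers(30, lo - 20))
            hn = "HNPYP" + str(rng.choice(["T", "S"]))
            residues[hn_start - 1:hn_start - 1 + len(hn)] = list(hn)
        seq = "".join(residues)
        hits = motif_scan(seq, _WFXNXR)
        if len(hits) != 1 or hits[0].start != motif_start:
            continue
        if not call_globular(kd_profile(seq, window=19)).globular:
            continue
        return SyntheticProtein(seq, "HD1" if with_hnpypts else "HD2",
                                motif_start, hn_start)
    return None


def generate_hd_protein(cfg: SyntheticProteinConfig,
                        rng: Optional[np.random.Generator] = None) -> SyntheticProtein:
    """Generate one homeodomain-like protein with ground-truth annotation.

    Guarantees by construction (rejection sampling): exactly one WFXNXR
    occurrence, placed inside the configured window; globular call under
    the default transmembrane detector; HD1 sequences additionally carry
    one HNPYPT/S motif N-terminal of the homeodomain.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.hd_class == "HD2":
        length = int(rng.integers(*cfg.hd2_length_range, endpoint=True))
    else:
        length = int(rng.integers(*cfg.hd2_length_range, endpoint=True)
                     + rng.integers(*cfg.hd1_extra_range, endpoint=True))
    out = _draw_sequence(length, cfg.motif_window, cfg.hd_class == "HD1", rng)
    if out is None:
        raise RuntimeError("could not generate a conforming sequence; "
                           "check the configured windows and lengths")
    out.hd_class = cfg.hd_class
    return out


def generate_hd_pair(cfg: SyntheticProteinConfig) -> tuple[SyntheticProtein,
                                                           SyntheticProtein]:
    """A coupled HD1/HD2 draw: length(HD1) - length(HD2) in the configured range."""
    rng = np.random.default_rng(cfg.seed)
    hd2_len = int(rng.integers(*cfg.hd2_length_range, endpoint=True))
    extra = int(rng.integers(*cfg.hd1_extra_range, endpoint=True))
    hd2 = _draw_sequence(hd2_len, MOTIF_WINDOWS["HD2"], False, rng)
    hd1 = _draw_sequence(hd2_len + extra, MOTIF_WINDOWS["HD1"], True, rng)
    if hd1 is None or hd2 is None:
        raise RuntimeError("could not generate a conforming HD1/HD2 pair")
    return hd1, hd2


def generate_allele_series(cfg: SyntheticProteinConfig, n_alleles: int,
                           ) -> list[SyntheticProtein]:
    """Allelic variants sharing a core but divergent at the N-terminus.

    Emulates the reported variability of the N-terminal dimerization
    domain between alleles: each variant resamples the first
    ``n_term_length`` residues of a common backbone at rate
    ``n_term_variability``, leaving the homeodomain region untouched.
    """
    rng = np.random.default_rng(cfg.seed)
    base = generate_hd_protein(cfg, rng)
    variants: list[SyntheticProtein] = []
    limit = min(cfg.n_term_length, cfg.motif_window[0] - 1,
                (base.hnpypts_start or base.length) - 1)
    for _ in range(n_alleles):
        for _attempt in range(100):
            residues = list(base.sequence)
            for i in range(limit):
                if rng.random() < cfg.n_term_variability:
                    residues[i] = str(rng.choice(_BG_RESIDUES, p=_BG_WEIGHTS))
            seq = "".join(residues)
            hits = motif_scan(seq, _WFXNXR)
            if len(hits) == 1 and call_globular(kd_profile(seq, 19)).globular:
                variants.append(SyntheticProtein(seq, base.hd_class,
                                                 base.motif_start,
                                                 base.hnpypts_start))
                break
        else:
            raise RuntimeError("could not derive a conforming allelic variant")
    return variants
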