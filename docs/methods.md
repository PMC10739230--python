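# Methods

## The tetrapolar compatibility model

Sexual compatibility is modelled over two unlinked multiallelic loci.
A monokaryon carries one allele at each locus (`AxBy`); two monokaryons
are compatible iff they differ at both loci.  A dikaryon is an unordered
pair of nuclei heteroallelic at both loci; it dikaryotizes a monokaryon
iff at least one nucleus is compatible with it (the Buller "either
nucleus" rule — the convention in the field; nothing in the crossing
data distinguishes a stricter rule, so the OR rule is adopted).
Meiosis of a dikaryon `AxBx + AyBy` releases all four tester types
`{AxBx, AxBy, AyBx, AyBy}` because the loci assort freely.  Self-crosses
are defined (always incompatible) rather than rejected, matching the
`−` diagonal convention of crossing tables.  Partial or unilateral
compatibility, nuclear-migration kinetics and clamp morphology are out
of model.

## From crossing matrices to allele counts

Observed `+`/`−` matrices are compiled to constraints over unknown
allele classes:

* `+(m, m′)`: `A(m) ≠ A(m′)` and `B(m) ≠ B(m′)`;
* `−(m, m′)`: `A(m) = A(m′)` or `B(m) = B(m′)`;
* panel structure for four testers `(m1..m4)` of one isolate:
  `A(m1)=A(m2)`, `A(m3)=A(m4)`, `B(m1)=B(m3)`, `B(m2)=B(m4)`, with the
  two A classes and two B classes distinct.

Missing cells contribute nothing.  Diagonal `+` cells and conflicting
symmetric records are inconsistencies, reported with their coordinates.
Di–mon rows are deliberately excluded from constraint extraction: a
di–mon `+` only says *some* nucleus was compatible, so these rows are
used for consistency checking, never for allele labelling.

**Propagation.**  Equalities are merged with a union-find structure per
locus.  A disjunction whose A branch is contradicted by an accumulated
inequality (the pair's A classes are known distinct) is resolved into a
forced B merge, and vice versa, repeated to fixpoint.  This formalizes
the classical deduction pattern "these two panels mate with both of each
other's A classes, so their shared incompatibilities must be shared B
alleles".  If both branches of a disjunction are blocked the instance is
unsatisfiable and the offending cell is named.

**Minimization.**  "At least N alleles" is read as the minimum of
distinct classes over all consistent assignments.  After propagation the
problem is a coupled graph-coloring: color the A-roots and B-roots so
that inequality edges separate colors and every unresolved disjunction
is satisfied by an equality at one locus.  The solver iteratively
deepens on the total `n_A + n_B`, starting from greedy-clique lower
bounds per locus, and for each split runs a backtracking search over
canonical restricted-growth colorings (colors tried in ascending order,
so ties among equally minimal assignments resolve to the
lexicographically smallest labelling per locus; classes are then named
A1, A2, ... by first appearance in row order).  Uniqueness up to
relabeling is decided by counting canonical solutions at the optimum
(capped at two).  Per-monokaryon flags distinguish classes fully forced
by the data from identifications chosen during minimization.

An independent exhaustive oracle (`brute_force_oracle`) enumerates raw
restricted-growth partitions of the monokaryons per locus with
constraint and best-sum pruning, and refuses instances above 12
monokaryons.  It shares no code with the propagation/minimization path
and anchors the property tests (200 random instances per run).

**Di–mon consistency.**  For a di–mon row the checker enumerates all
dikaryons over a bounded allele universe — the alleles observed among
the testers plus two fresh alleles per locus — and reports which
genotypes reproduce the row.  Two fresh alleles per locus are exhaustive
in the relevant sense: the compatibility predicate only distinguishes
equal/unequal to observed alleles, so additional novel alleles add no
expressive power.  "A novel allele is forced" is asserted only when
*every* satisfying dikaryon uses one; a single counterexample genotype
refutes it.

**Caveat on the stated crosses.**  The M-14/M-17 records are encoded as
all-compatible blocks exactly as stated in the source records; had any
unreported incompatibility existed among them, the minimal matB count
could differ.  The inference faithfully reflects the records as given.

## Synthetic populations

`simulate_population` draws dikaryotic isolates from allele pools at
the two loci (rejection until heteroallelic at both), derives the four
tester types per isolate, and predicts the full pairwise mon–mon matrix
(optionally a di–mon table against the first isolate's panel).  Defaults
mirror the species' reported biology: pools of 24 matA and 21 matB
alleles, 17 isolates, uniform allele frequencies (a Dirichlet option
exists because natural frequencies are skewed; it is an extension, not a
default), and error-free scoring — clamp scoring is treated as reliable.
Scoring noise, when enabled, flips each off-diagonal cell independently
with the configured probability; the diagonal is left `−` because a
self-cross cannot form clamps, so a flipped diagonal would be a
physically impossible observation rather than a plausible mis-score.
A mandatory seed drives a single `numpy` generator; equal seeds give
bit-identical tables, panels and ground truth.

Round-trip guarantee: with complete four-tester panels, full pairwise
crossing and no noise, inference recovers exactly the distinct alleles
present among the testers — every pair of truly distinct A classes meets
in at least one fully heteroallelic (`+`) cross because each A class
appears with both of its panel's B alleles.  The recovery tests and the
acceptance properties rely on this; isolated monokaryons without panel
structure can genuinely underdetermine the counts, which the simulator
does not emulate.

## Synthetic homeodomain-like proteins

`generate_hd_protein` emulates the reported structural profile of the
matA proteins, not their actual sequences: residues are drawn from a
hydrophilic-biased background (sampling weights decay exponentially with
Kyte–Doolittle hydropathy, rate 0.6 per unit), one `WFXNXR` instance is
embedded at a uniform position inside the class window (HD1: residues
125–175; HD2: 145–200 — the species-specific windows; the wider
cross-species ranges 120–190/140–195 are not used), and HD1 sequences
additionally receive one `HNPYP[TS]` motif N-terminal of the
homeodomain.  HD2 backbone lengths are uniform on 230–280 aa (consistent
with homeobox fragments reported near residue 180); HD1 partners are
longer by a uniform 40–50 aa draw.  Rejection sampling against the
package's own motif scanner and transmembrane detector guarantees
exactly one `WFXNXR` occurrence and a globular call by construction —
deliberately, since these are the invariants downstream analyses assume.
`generate_allele_series` derives allelic variants by resampling the
first 60 residues (the variable dimerization N-terminus) at rate 0.5 per
residue; the divergence level is a free parameter with no measured
counterpart, chosen as a clearly-divergent default.

What passing tests on these sequences do **not** show: real HD proteins
have conserved secondary structure, biased dipeptide statistics and
evolutionary covariation none of which the generator models; the
generator demonstrates the analysis pipeline's correctness, not
biological realism of the sequences.

## Protein analyses: numerical choices

* **Motif scanner** — linear patterns over the 20-aa alphabet with `X`
  wildcards and `[..]` alternative sets; all (including overlapping)
  matches reported at 1-based positions, via an overlap-tolerant
  lookahead regex, property-checked against a position-by-position
  reference scanner.  Invalid residues are errors naming the position.
* **Hydropathy** — sliding arithmetic mean of the canonical
  Kyte–Doolittle residue values; window must be odd (default 19, the
  conventional transmembrane-scan width).  Transmembrane call: any
  maximal run of window centres above 1.6, the conventional cutoff for
  a 19-residue window; globular = no such run.  The method source names
  the approach but not its parameters, so the conventional values are
  adopted and exposed as flags.
* **NLS screen** — a pure composition heuristic: windows (default 7)
  whose K+R or P+H fraction reaches 4/7, merged when overlapping.  The
  defaults are design choices with no canonical parameterization; the
  printed HD2 homeobox fragment, for instance, only shows its mildly
  basic character at a relaxed fraction of 2/7.  No k-NN localization
  classifier is reimplemented, so per-compartment localization
  percentages are out of scope.
* **Length comparison** — descriptive only (mean and range of HD1−HD2
  differences; paired when set sizes match), no thresholding.
* **Locus model / GFF3** — gene order and orientation only (`mip`, 1–3
  `hd` genes, `fg`; dual `hd1` copies must be divergently oriented).
  Coordinates are ordinal placeholders (1 kb genes, 500 bp spacers) on a
  per-strain scaffold because no base-pair coordinates are available;
  the GFF3 encodes structure, not geometry.

## Problem sizes

The bundled-data analyses are instant (24 monokaryons at most).  The
statistical test batteries use 200 random instances of up to 12
monokaryons against the exhaustive oracle, 100 simulate→infer
round-trips with pools of 2–8 alleles and 1–6 isolates, and 20 synthetic
protein pairs — sizes at which the oracle remains exact and the whole
suite runs in seconds while exercising every code path at the same
constraint densities as the real records.

## Known limitations

* The minimization is exponential in the worst case; it is exact and
  fast at study scale (tens of monokaryons) but not intended for
  hundreds.
* Allele counts are minimal consistent counts, not estimates of
  population allele richness; no frequency or likelihood model is fitted.
* The multiple-alignment, secondary-structure, signal-peptide and
  localization-classifier analyses of the original workflow depend on
  external tools and training data and are intentionally absent.
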