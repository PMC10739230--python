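# tetramate

Tetrapolar mating-compatibility genetics of the oyster mushroom
*Pleurotus ostreatus*: crossing-table analysis, constraint-based allele
counting, and sequence analyses of the matA homeodomain proteins.

## The problem

Homobasidiomycete fungi like *P. ostreatus* mate under a **tetrapolar**
system: two unlinked multiallelic loci, *matA* (HD1/HD2 homeodomain
transcription factors) and *matB* (pheromones and receptors), control
sexual compatibility.  Two haploid monokaryons fuse into a fertile,
clamp-bearing dikaryon only when they differ at **both** loci
(`AxBx × AyBy` with `x ≠ y` at each locus); a dikaryon can also
dikaryotize a monokaryon if either of its nuclei is compatible with it
(di–mon cross, the Buller phenomenon).

Mycologists score crosses as `+`/`−` matrices of clamp formation between
the four monobasidiospore testers (`AxBx, AxBy, AyBx, AyBy`) derived
from each wild dikaryon.  The question this package answers from such a
matrix: **how many distinct alleles must each locus carry?**  Each `+`
cell forces `A(m) ≠ A(m′) ∧ B(m) ≠ B(m′)`; each `−` cell the disjunction
`A(m) = A(m′) ∨ B(m) = B(m′)`; the panel structure adds the meiotic
equalities.  "At least *N* alleles" is the minimum number of allele
classes over all assignments consistent with every observation, computed
exactly by union-find propagation of forced identities followed by a
backtracking search over canonical restricted-growth labelings, and
verified against an independent exhaustive oracle.

The package also implements the companion protein analyses for the matA
gene products: a wildcard motif scanner (the conserved homeodomain
DNA-binding motif `WFXNXR`, and `HNPYP[TS]` found in HD1 only),
Kyte–Doolittle hydropathy with a globular/transmembrane call, a
composition heuristic for nuclear-localization-signal candidates
(K/R- or P/H-enriched windows), HD1-vs-HD2 length comparison, and a gene
cassette model of the matA locus (`mip — hd genes — fg`) with GFF3
export.  A synthetic-data module simulates the whole study design
(allele pools → dikaryotic isolates → tester panels → crossing matrices,
and homeodomain-like proteins with ground truth) so every stage is
testable end to end.

## Worked example

The package bundles the crossing records of a Moscow-region collection:
five natural dikaryotic isolates typed via four-tester panels (M-8, M-9,
M-13, M-14, M-17), their mutual mon–mon crosses, their crosses against
the reference panel of strain M-38, and twelve further isolates crossed
di–mon against M-38.

```
$ tetramate reproduce
Minimal allele counts, 20 natural-isolate testers (panels M-8, M-9, M-13, M-14, M-17):
  n_A = 10   n_B = 8   (unique up to relabeling: True)
  B-class identities forced by propagation involve: ['M-13.m1', 'M-13.m2', 'M-8.m1', 'M-8.m2']
Including the four M-38 reference testers:
  n_A = 12   n_B = 10
Di-mon rows vs the M-38 panel: 12/12 consistent; 0 force a novel allele.
WFXNXR scan of the printed HD2 homeobox fragments:
  PC15: WFQNHR at fragment position 15 (residue 193 of the protein)
  PC9: WFQNHR at fragment position 15 (residue 191 of the protein)
```

Reading the output: the twenty natural testers cannot be explained with
fewer than **ten matA** and **eight matB** allele classes, and that
minimal assignment is unique up to renaming.  Eight (not ten) matB
classes arise because the M-8 × M-13 block is only half compatible
(8 of 16 crosses `+`): each M-13 tester mates with both matA classes of
the M-8 panel, so its incompatibilities can only be explained by shared
matB alleles — an identification *forced* by propagation, not chosen
during minimization.  Adding the reference panel raises the counts to
12/10, since all eighty crosses against it succeeded.  The di–mon rows
are consistent with compatible dikaryons but, being all-`+`, never force
a novel allele.  Both printed HD2 homeobox fragments carry the
DNA-binding motif `WFXNXR` (as `WFQNHR`) at fragment position 15.

The same pipeline is available as a library (`tetramate.infer`,
`tetramate.motif_scan`, ...) and as further subcommands
(`tetramate infer/predict/synth/protein`).  The numbered scripts under
`analysis/` run the full study: table structure (`01`), allele inference
(`02`), simulation round-trips (`03`), and protein analyses (`04`),
writing their tables under `results/`.

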