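"""Inference of allele identity classes from +/- compatibility matrices.

A mon--mon crossing matrix constrains the unknown *matA*/*matB* alleles of
the monokaryons:

* a PLUS cell means the pair differs at **both** loci (two inequality
  constraints);
* a MINUS cell means the pair shares an allele at *matA* **or** at *matB*
  (a disjunctive constraint);
* a four-tester panel contributes its meiotic structure (testers 1/2 and
  3/4 share the A allele, 1/3 and 2/4 the B allele, and the two A classes
  and two B classes within a panel differ).

"At least N alleles" is formalized as the minimum number of distinct
allele classes over all assignments consistent with every observation.
:func:`propagate` performs unit propagation (union-find merges of forced
identities -- the formal counterpart of deductions like "these two strains
must carry the same matB alleles"), and :func:`minimal_assignment` finishes
with an exact backtracking search over canonical restricted-growth
colorings.  :func:`brute_force_oracle` is an independent exhaustive solver
used for verification on small instances.

Di--mon rows constrain but never label alleles: the allele counts come from
mon--mon-typed monokaryons only, and :func:`check_dimon_consistency` only
reports which dikaryon genotypes could explain each di--mon row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .mating import AlleleLabel, Dikaryon, MatingGenotype, dimon_compatible
from .tables import Cell, CrossTable, PanelSpec, RowKind

__all__ = [
    "InconsistencyError",
    "ConstraintSet",
    "AlleleAssignment",
    "DimonReport",
    "build_constraints",
    "propagate",
    "minimal_assignment",
    "infer",
    "check_dimon_consistency",
    "brute_force_oracle",
]


class InconsistencyError(ValueError):
    """The observations admit no allele assignment under the tetrapolar model."""


# ---------------------------------------------------------------------------
# constraint extraction

@dataclass
class ConstraintSet:
    """Constraints over monokaryon allele classes extracted from tables.

    Constraint triples reference monokaryons by index into ``monokaryons``.
    ``equalities``/``inequalities`` carry a locus tag ("A" or "B") and a
    human-readable source; ``disjunctions`` (i shares A with j) OR
    (i shares B with j) come from MINUS cells.
    """

    monokaryons: list[str]
    equalities: list[tuple[str, int, int, str]] = field(default_factory=list)
    inequalities: list[tuple[str, int, int, str]] = field(default_factory=list)
    disjunctions: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.monokaryons)

    def index(self, label: str) -> int:
        return self.monokaryons.index(label)


def build_constraints(
    tables: Union[CrossTable, Iterable[CrossTable]],
    panels: Sequence[PanelSpec] = (),
) -> ConstraintSet:
    """Extract a :class:`ConstraintSet` from mon--mon tables plus panel structure.

    Dikaryon rows are ignored here (see :func:`check_dimon_consistency`).
    Monokaryons are numbered by first appearance (rows, then columns, per
    table in order), which fixes the canonical labelling downstream.
    Symmetric duplicate cells are de-duplicated; a PLUS on the diagonal or
    a conflicting symmetric pair raises :class:`InconsistencyError`.
    """
    if isinstance(tables, CrossTable):
        tables = [tables]
    tables = list(tables)

    order: list[str] = []
    seen: dict[str, int] = {}

    def _add(label: str) -> int:
        if label not in seen:
            seen[label] = len(order)
            order.append(label)
        return seen[label]

    for t in tables:
        for r, kind in zip(t.row_labels, t.row_kinds):
            if kind is RowKind.MONOKARYON:
                _add(r)
        for c in t.col_labels:
            _add(c)

    cs = ConstraintSet(monokaryons=order)
    cell_values: dict[frozenset, tuple[Cell, str]] = {}

    for t in tables:
        for i, (r, kind) in enumerate(zip(t.row_labels, t.row_kinds)):
            if kind is not RowKind.MONOKARYON:
                continue
            for j, c in enumerate(t.col_labels):
                v = t.entries[i][j]
                if v is Cell.MISSING:
                    continue
                src = f"{r} x {c}"
                if r == c:
                    if v is Cell.PLUS:
                        raise InconsistencyError(
                            f"self-cross {src} scored PLUS: self-compatibility is "
                            "impossible under the tetrapolar model")
                    continue  # diagonal MINUS carries no information
                key = frozenset((r, c))
                if key in cell_values:
                    prev, prev_src = cell_values[key]
                    if prev is not v:
                        raise InconsistencyError(
                            f"conflicting records for the pair {src} "
                            f"(previously {prev_src}: {prev.value})")
                    continue
                cell_values[key] = (v, src)
                a, b = _add(r), _add(c)
                if v is Cell.PLUS:
                    cs.inequalities.append(("A", a, b, src))
                    cs.inequalities.append(("B", a, b, src))
                else:
                    cs.disjunctions.append((a, b, src))

    for p in panels:
        if not all(t in seen for t in p.testers):
            continue  # panel not represented in these tables
        t1, t2, t3, t4 = (seen[t] for t in p.testers)
        src = f"panel {p.isolate}"
        cs.equalities += [("A", t1, t2, src), ("A", t3, t4, src),
                          ("B", t1, t3, src), ("B", t2, t4, src)]
        cs.inequalities += [("A", t1, t3, src), ("B", t1, t2, src)]
    return cs


# ---------------------------------------------------------------------------
# propagation

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[max(rx, ry)] = min(rx, ry)
        return True


@dataclass
class PropagatedConstraints:
    """Fixpoint of unit propagation over a :class:`ConstraintSet`."""

    source: ConstraintSet
    uf_a: _UnionFind
    uf_b: _UnionFind
    #: merges forced by resolving a disjunction whose other branch was
    #: contradicted: (locus, i, j, source cell)
    forced_merges: list[tuple[str, int, int, str]]
    #: disjunctions neither satisfied nor resolved by propagation
    unresolved: list[tuple[int, int, str]]

    def same_class(self, locus: str, m1: str, m2: str) -> bool:
        uf = self.uf_a if locus == "A" else self.uf_b
        return uf.find(self.source.index(m1)) == uf.find(self.source.index(m2))


def propagate(cs: ConstraintSet) -> PropagatedConstraints:
    """Resolve disjunctions whose A- (or B-) branch contradicts the inequalities.

    Classic unit propagation: apply all equalities via union-find, then
    repeatedly convert each MINUS-cell disjunction whose "share A" branch
    is blocked by an accumulated A-inequality into a forced B merge (and
    vice versa) until a fixpoint.  Raises :class:`InconsistencyError` naming
    the offending cell if both branches of a disjunction are blocked or an
    inequality collapses.
    """
    uf_a, uf_b = _UnionFind(cs.n), _UnionFind(cs.n)
    for locus, i, j, _src in cs.equalities:
        (uf_a if locus == "A" else uf_b).union(i, j)

    forced: list[tuple[str, int, int, str]] = []
    pending = list(cs.disjunctions)

    def _check_inequalities() -> None:
        for locus, i, j, src in cs.inequalities:
            uf = uf_a if locus == "A" else uf_b
            if uf.find(i) == uf.find(j):
                raise InconsistencyError(
                    f"constraint from {src} violated: mat{locus} classes of the "
                    "pair were merged by other observations")

    _check_inequalities()
    changed = True
    while changed:
        changed = False
        ineq_a = {frozenset((uf_a.find(i), uf_a.find(j)))
                  for locus, i, j, _ in cs.inequalities if locus == "A"}
        ineq_b = {frozenset((uf_b.find(i), uf_b.find(j)))
                  for locus, i, j, _ in cs.inequalities if locus == "B"}
        still: list[tuple[int, int, str]] = []
        for i, j, src in pending:
            if uf_a.find(i) == uf_a.find(j) or uf_b.find(i) == uf_b.find(j):
                continue  # satisfied
            a_blocked = frozenset((uf_a.find(i), uf_a.find(j))) in ineq_a
            b_blocked = frozenset((uf_b.find(i), uf_b.find(j))) in ineq_b
            if a_blocked and b_blocked:
                raise InconsistencyError(
                    f"cell {src} is MINUS but both shared-A and shared-B "
                    "explanations are contradicted by PLUS cells")
            if a_blocked:
                uf_b.union(i, j)
                forced.append(("B", i, j, src))
                changed = True
            elif b_blocked:
                uf_a.union(i, j)
                forced.append(("A", i, j, src))
                changed = True
            else:
                still.append((i, j, src))
        pending = still
        _check_inequalities()

    return PropagatedConstraints(cs, uf_a, uf_b, forced, pending)


# ---------------------------------------------------------------------------
# exact minimization

@dataclass
class AlleleAssignment:
    """A minimal consistent assignment of allele classes.

    Canonical class labels ("A1", "A2", ... / "B1", ...) are issued by
    first appearance in monokaryon order, so output is deterministic.
    ``forced`` records, per locus and monokaryon, whether the monokaryon's
    class is determined by propagation alone ("forced") or involves an
    identification chosen during minimization ("chosen").
    """

    monokaryons: list[str]
    a_class: dict[str, str]
    b_class: dict[str, str]
    n_a: int
    n_b: int
    forced: dict[str, dict[str, str]]
    forced_merges: list[tuple[str, str, str, str]]
    unique_up_to_relabeling: bool

    def genotype(self, monokaryon: str) -> MatingGenotype:
        return MatingGenotype(
            a=AlleleLabel("A", self.a_class[monokaryon]),
            b=AlleleLabel("B", self.b_class[monokaryon]),
        )

    def genotypes(self) -> dict[str, MatingGenotype]:
        return {m: self.genotype(m) for m in self.monokaryons}


def _greedy_clique_bound(n_nodes: int, edges: set[frozenset]) -> int:
    """Greedy max-clique lower bound for the chromatic number."""
    adj = {v: set() for v in range(n_nodes)}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    best = 1 if n_nodes else 0
    for v in sorted(adj, key=lambda v: -len(adj[v])):
        clique = {v}
        for u in sorted(adj[v], key=lambda u: -len(adj[u])):
            if all(u in adj[w] for w in clique):
                clique.add(u)
        best = max(best, len(clique))
    return best


def _color_solutions(
    n_a_roots: int,
    n_b_roots: int,
    edges_a: set[frozenset],
    edges_b: set[frozenset],
    disjunctions: list[tuple[int, int, int, int]],
    max_a: int,
    max_b: int,
    limit: int,
) -> list[tuple[list[int], list[int]]]:
    """Canonical (restricted-growth) colorings satisfying all constraints.

    Colors A roots in order, then B roots; a disjunction (ai, aj, bi, bj)
    is checked once its last endpoint is colored.  Returns at most
    ``limit`` solutions in lexicographic order.
    """
    adj_a: dict[int, list[int]] = {v: [] for v in range(n_a_roots)}
    for e in edges_a:
        a, b = tuple(e)
        adj_a[max(a, b)].append(min(a, b))
    adj_b: dict[int, list[int]] = {v: [] for v in range(n_b_roots)}
    for e in edges_b:
        a, b = tuple(e)
        adj_b[max(a, b)].append(min(a, b))
    # disjunctions indexed by their last-assigned B root
    disj_at: dict[int, list[tuple[int, int, int, int]]] = {}
    for d in disjunctions:
        disj_at.setdefault(max(d[2], d[3]), []).append(d)

    color_a = [-1] * n_a_roots
    color_b = [-1] * n_b_roots
    out: list[tuple[list[int], list[int]]] = []

    def go_b(v: int, used: int) -> bool:
        if v == n_b_roots:
            out.append((color_a.copy(), color_b.copy()))
            return len(out) >= limit
        for c in range(min(used + 1, max_b)):
            if any(color_b[u] == c for u in adj_b[v]):
                continue
            color_b[v] = c
            ok = True
            for ai, aj, bi, bj in disj_at.get(v, ()):
                if color_a[ai] != color_a[aj] and color_b[bi] != color_b[bj]:
                    ok = False
                    break
            if ok and go_b(v + 1, max(used, c + 1)):
                return True
        color_b[v] = -1
        return False

    def go_a(v: int, used: int) -> bool:
        if v == n_a_roots:
            return go_b(0, 0)
        for c in range(min(used + 1, max_a)):
            if any(color_a[u] == c for u in adj_a[v]):
                continue
            color_a[v] = c
            if go_a(v + 1, max(used, c + 1)):
                return True
        color_a[v] = -1
        return False

    go_a(0, 0)
    return out


def minimal_assignment(prop: PropagatedConstraints) -> AlleleAssignment:
    """Exact minimal-allele-count assignment over a propagated constraint set.

    Minimizes n_A + n_B (iterative deepening from per-locus clique lower
    bounds; for each total, splits with smaller n_A are tried first), with
    exact backtracking over unresolved disjunctions and optional class
    identifications.  Ties among equally minimal assignments are broken by
    the lexicographically smallest restricted-growth labelling per locus.
    """
    cs = prop.source
    n = cs.n

    def roots_in_order(uf: _UnionFind) -> tuple[list[int], dict[int, int]]:
        roots: list[int] = []
        index: dict[int, int] = {}
        for m in range(n):
            r = uf.find(m)
            if r not in index:
                index[r] = len(roots)
                roots.append(r)
        return roots, index

    ra, ia = roots_in_order(prop.uf_a)
    rb, ib = roots_in_order(prop.uf_b)

    edges_a = {frozenset((ia[prop.uf_a.find(i)], ia[prop.uf_a.find(j)]))
               for locus, i, j, _ in cs.inequalities if locus == "A"}
    edges_b = {frozenset((ib[prop.uf_b.find(i)], ib[prop.uf_b.find(j)]))
               for locus, i, j, _ in cs.inequalities if locus == "B"}
    disjs = [(ia[prop.uf_a.find(i)], ia[prop.uf_a.find(j)],
              ib[prop.uf_b.find(i)], ib[prop.uf_b.find(j)])
             for i, j, _ in prop.unresolved]

    lb_a = _greedy_clique_bound(len(ra), edges_a)
    lb_b = _greedy_clique_bound(len(rb), edges_b)

    solution: Optional[tuple[list[int], list[int]]] = None
    extra = 0
    for total in range(lb_a + lb_b, len(ra) + len(rb) + 1):
        feasible: list[tuple[list[int], list[int]]] = []
        for n_a in range(lb_a, min(len(ra), total - lb_b) + 1):
            n_b = total - n_a
            if not (lb_b <= n_b <= len(rb)):
                continue
            sols = _color_solutions(len(ra), len(rb), edges_a, edges_b,
                                    disjs, n_a, n_b, limit=2)
            feasible.extend(sols)
            if sols and solution is None:
                solution = sols[0]
        if solution is not None:
            # dedupe: the same coloring can appear under several splits
            uniq = {(tuple(a), tuple(b)) for a, b in feasible}
            extra = len(uniq)
            break
    assert solution is not None  # total == len(ra)+len(rb) is always feasible

    color_a, color_b = solution
    n_a_used = max(color_a) + 1 if color_a else 0
    n_b_used = max(color_b) + 1 if color_b else 0

    a_class = {cs.monokaryons[m]: f"A{color_a[ia[prop.uf_a.find(m)]] + 1}"
               for m in range(n)}
    b_class = {cs.monokaryons[m]: f"B{color_b[ib[prop.uf_b.find(m)]] + 1}"
               for m in range(n)}

    # a class whose color was given to more than one propagation root owes
    # its identity to a minimization choice, not to the data alone
    chosen_a = {c for c, k in _counts(color_a).items() if k > 1}
    chosen_b = {c for c, k in _counts(color_b).items() if k > 1}
    forced = {
        "A": {cs.monokaryons[m]:
              "chosen" if color_a[ia[prop.uf_a.find(m)]] in chosen_a else "forced"
              for m in range(n)},
        "B": {cs.monokaryons[m]:
              "chosen" if color_b[ib[prop.uf_b.find(m)]] in chosen_b else "forced"
              for m in range(n)},
    }
    forced_merges = [(locus, cs.monokaryons[i], cs.monokaryons[j], src)
                     for locus, i, j, src in prop.forced_merges]
    return AlleleAssignment(
        monokaryons=list(cs.monokaryons),
        a_class=a_class,
        b_class=b_class,
        n_a=n_a_used,
        n_b=n_b_used,
        forced=forced,
        forced_merges=forced_merges,
        unique_up_to_relabeling=(extra == 1),
    )


def _counts(xs: list[int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for x in xs:
        out[x] = out.get(x, 0) + 1
    return out


def infer(
    tables: Union[CrossTable, Iterable[CrossTable]],
    panels: Sequence[PanelSpec] = (),
    include: Optional[Sequence[str]] = None,
    exclude: Optional[Sequence[str]] = None,
) -> AlleleAssignment:
    """End-to-end inference: constraints -> propagation -> minimal assignment.

    ``include``/``exclude`` restrict the analysis to matching monokaryons
    (prefix match on the isolate name, so ``exclude=["M-38"]`` drops the
    whole reference panel) by masking their cells before extraction.
    """
    if isinstance(tables, CrossTable):
        tables = [tables]
    tables = list(tables)

    def _keep(label: str) -> bool:
        iso = label.split(".")[0]
        if include is not None and iso not in include and label not in include:
            return False
        if exclude is not None and (iso in exclude or label in exclude):
            return False
        return True

    filtered = []
    for t in tables:
        rows = [r for r, k in zip(t.row_labels, t.row_kinds)
                if k is RowKind.MONOKARYON and _keep(r)]
        cols = [c for c in t.col_labels if _keep(c)]
        if rows and cols:
            filtered.append(t.subtable(rows, cols))
    cs = build_constraints(filtered, panels)
    return minimal_assignment(propagate(cs))


# ---------------------------------------------------------------------------
# di--mon consistency

@dataclass
class DimonReport:
    """Which dikaryon genotypes could explain one di--mon cross row.

    Enumeration runs over a bounded allele universe: the alleles observed
    among the testers plus ``fresh`` novel alleles per locus.  This is
    exhaustive in the relevant sense -- the compatibility predicate only
    distinguishes equal/unequal to observed alleles, so all novel alleles
    of a locus are interchangeable.
    """

    dikaryon: str
    satisfiable: bool
    n_satisfying: int
    forced_novel_a: bool
    forced_novel_b: bool
    examples: list[str]


def check_dimon_consistency(
    table: CrossTable,
    tester_genotypes: Mapping[str, MatingGenotype],
    fresh: int = 2,
    max_examples: int = 4,
) -> list[DimonReport]:
    """Enumerate explaining dikaryon genotypes for every di--mon row.

    ``forced_novel_a``/``_b`` are True only when *every* satisfying
    dikaryon carries at least one allele outside the observed set at that
    locus; a single counterexample genotype suffices to refute "the row
    proves a novel allele".
    """
    a_obs = sorted({g.a for g in tester_genotypes.values()},
                   key=lambda x: x.sort_key())
    b_obs = sorted({g.b for g in tester_genotypes.values()},
                   key=lambda x: x.sort_key())
    a_new = [AlleleLabel("A", f"Anew{k + 1}") for k in range(fresh)]
    b_new = [AlleleLabel("B", f"Bnew{k + 1}") for k in range(fresh)]
    universe = [MatingGenotype(a, b)
                for a in a_obs + a_new for b in b_obs + b_new]

    reports: list[DimonReport] = []
    for i, (label, kind) in enumerate(zip(table.row_labels, table.row_kinds)):
        if kind is not RowKind.DIKARYON:
            continue
        observed = [(tester_genotypes[c], table.entries[i][j])
                    for j, c in enumerate(table.col_labels)
                    if table.entries[i][j] is not Cell.MISSING]
        satisfying: list[Dikaryon] = []
        novel_a_always = True
        novel_b_always = True
        for g1, g2 in itertools.combinations(universe, 2):
            if g1.a == g2.a or g1.b == g2.b:
                continue
            d = Dikaryon(g1, g2)
            if all((Cell.PLUS if dimon_compatible(d, m) else Cell.MINUS) is v
                   for m, v in observed):
                satisfying.append(d)
                if not any(x.a in a_new for x in (g1, g2)):
                    novel_a_always = False
                if not any(x.b in b_new for x in (g1, g2)):
                    novel_b_always = False
        reports.append(DimonReport(
            dikaryon=label,
            satisfiable=bool(satisfying),
            n_satisfying=len(satisfying),
            forced_novel_a=bool(satisfying) and novel_a_always,
            forced_novel_b=bool(satisfying) and novel_b_always,
            examples=[str(d) for d in satisfying[:max_examples]],
        ))
    return reports


# ---------------------------------------------------------------------------
# verification oracle

def brute_force_oracle(cs: ConstraintSet, max_monokaryons: int = 12) -> tuple[int, int]:
    """True minimal (n_A, n_B) by exhaustive enumeration; for tests only.

    Enumerates restricted-growth A-partitions of the monokaryons with
    constraint and best-sum pruning; for each complete A-partition the
    disjunctions not satisfied via A become forced B equalities and the
    B-partitions are enumerated the same way.  Independent of
    :func:`propagate`/:func:`minimal_assignment`.
    """
    n = cs.n
    if n > max_monokaryons:
        raise ValueError(f"instance with {n} monokaryons exceeds the oracle "
                         f"limit of {max_monokaryons}")

    eq = {"A": [[] for _ in range(n)], "B": [[] for _ in range(n)]}
    ne = {"A": [[] for _ in range(n)], "B": [[] for _ in range(n)]}
    for locus, i, j, _ in cs.equalities:
        eq[locus][max(i, j)].append(min(i, j))
    for locus, i, j, _ in cs.inequalities:
        ne[locus][max(i, j)].append(min(i, j))

    best: list[Optional[tuple[int, tuple[int, int]]]] = [None]

    def enum_b(colors_b: list[int], v: int, used: int, used_a: int,
               extra_eq: list[list[int]]) -> None:
        if v < n and best[0] is not None and used_a + max(used, 1) > best[0][0]:
            return
        if v == n:
            cand = (used_a + used, (used_a, used))
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        must = {colors_b[u] for u in eq["B"][v]} | {colors_b[u] for u in extra_eq[v]}
        if len(must) > 1:
            return
        banned = {colors_b[u] for u in ne["B"][v]}
        if must:
            c = must.pop()
            if c not in banned:
                colors_b[v] = c
                enum_b(colors_b, v + 1, used, used_a, extra_eq)
                colors_b[v] = -1
            return
        top = used + 1
        if best[0] is not None:
            top = min(top, best[0][0] - used_a)
        for c in range(top):
            if c in banned:
                continue
            colors_b[v] = c
            enum_b(colors_b, v + 1, max(used, c + 1), used_a, extra_eq)
            colors_b[v] = -1

    def enum_a(colors_a: list[int], v: int, used: int) -> None:
        if best[0] is not None and used + 1 >= best[0][0] and v < n:
            return
        if v == n:
            extra_eq: list[list[int]] = [[] for _ in range(n)]
            for i, j, _ in cs.disjunctions:
                if colors_a[i] != colors_a[j]:
                    extra_eq[max(i, j)].append(min(i, j))
            enum_b([-1] * n, 0, 0, used, extra_eq)
            return
        must = {colors_a[u] for u in eq["A"][v]}
        if len(must) > 1:
            return
        banned = {colors_a[u] for u in ne["A"][v]}
        if must:
            c = must.pop()
            if c not in banned:
                colors_a[v] = c
                enum_a(colors_a, v + 1, used)
                colors_a[v] = -1
            return
        for c in range(used + 1):
            if c in banned:
                continue
            colors_a[v] = c
            enum_a(colors_a, v + 1, max(used, c + 1))
            colors_a[v] = -1

    enum_a([-1] * n, 0, 0)
    if best[0] is None:
        raise InconsistencyError("no consistent allele assignment exists")
    return best[0][1]
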