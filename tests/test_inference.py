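"""Allele-class inference: constraints, propagation, minimization, oracle."""

import numpy as np
import pytest

from tetramate import fixtures
from tetramate.inference import (InconsistencyError, brute_force_oracle,
                                 build_constraints, check_dimon_consistency,
                                 infer, minimal_assignment, propagate)
from tetramate.mating import Dikaryon, parse_genotype
from tetramate.tables import (Cell, CrossTable, PanelSpec, RowKind,
                              parse_cross_table, predict_table)
from conftest import random_instance


def panel(iso, genos):
    return PanelSpec(iso, [f"{iso}.m{i}" for i in range(1, 5)],
                     [parse_genotype(s) for s in genos])


class TestBuildConstraints:
    def test_plus_cell_yields_two_inequalities(self):
        t = parse_cross_table(",m1,m2\nm1,?,+\nm2,+,?\n")
        cs = build_constraints(t)
        assert len(cs.inequalities) == 2
        assert {l for l, *_ in cs.inequalities} == {"A", "B"}
        assert cs.disjunctions == []

    def test_shared_b_block_constraint_counts(self, natural_tables, all_panels):
        """8 MINUS cells -> 8 disjunctions; 8 PLUS cells -> 8 inequality pairs."""
        t = natural_tables[0]
        m13 = [f"M-13.m{i}" for i in range(1, 5)]
        m8 = [f"M-8.m{i}" for i in range(1, 5)]
        cs = build_constraints(t.subtable(m13, m8))
        assert len(cs.disjunctions) == 8
        assert len(cs.inequalities) == 16  # 8 PLUS cells x two loci

    def test_plus_on_diagonal_is_inconsistent(self):
        t = parse_cross_table(",m1,m2\nm1,+,-\nm2,-,-\n")
        with pytest.raises(InconsistencyError, match="self-"):
            build_constraints(t)

    def test_conflicting_symmetric_cells_rejected(self):
        t = parse_cross_table(",m1,m2\nm1,-,+\nm2,-,-\n")
        with pytest.raises(InconsistencyError, match="conflicting"):
            build_constraints(t)

    def test_dikaryon_rows_contribute_nothing(self):
        t = parse_cross_table(",m1,m2\nD1,+,+\n", row_kinds=RowKind.DIKARYON)
        cs = build_constraints(t)
        assert cs.inequalities == [] and cs.disjunctions == []


class TestPropagate:
    def test_forced_shared_b_between_panels(self, natural_tables, all_panels):
        """The M-13 testers are forced onto the M-8 matB classes.

        Each M-13 tester is incompatible with an M-8 tester from which it
        is known to differ at matA (it mates with both A-classes of the
        M-8 panel), so the shared allele can only be at matB.
        """
        cs = build_constraints(natural_tables[0],
                               [p for p in all_panels if p.isolate != "M-38"])
        prop = propagate(cs)
        assert prop.same_class("B", "M-13.m1", "M-8.m1")
        assert prop.same_class("B", "M-13.m2", "M-8.m2")
        assert prop.same_class("B", "M-13.m3", "M-8.m1")
        assert not prop.same_class("B", "M-13.m1", "M-9.m1")
        forced_b = [x for x in prop.forced_merges if x[0] == "B"]
        assert forced_b  # identities deduced, not assumed

    def test_all_plus_table_merges_nothing(self):
        t = parse_cross_table(",m1,m2\nm1,-,+\nm2,+,-\n")
        prop = propagate(build_constraints(t))
        assert prop.forced_merges == [] and prop.unresolved == []

    def test_unsatisfiable_minus_cell_detected(self):
        # x-y is MINUS, but x differs from y at A (via PLUS chain with both
        # B partners equal... craft directly: PLUS forces A!=, B!=; then a
        # MINUS between the same pair is contradictory on both branches.
        t = CrossTable(["x", "y"], ["x", "y"],
                       [[Cell.MINUS, Cell.PLUS], [Cell.MINUS, Cell.MINUS]])
        with pytest.raises(InconsistencyError):
            propagate(build_constraints(t))


class TestMinimalAssignment:
    def test_natural_isolates_headline_counts(self, natural_tables, all_panels):
        """Twenty natural testers: ten matA classes, eight matB classes."""
        a = infer(natural_tables, all_panels, exclude=["M-38"])
        assert (a.n_a, a.n_b) == (10, 8)
        assert a.unique_up_to_relabeling
        # the B identifications between M-8 and M-13 were forced
        assert any(l == "B" and {x.split(".")[0] for x in (m1, m2)} ==
                   {"M-8", "M-13"} for l, m1, m2, _ in a.forced_merges)

    def test_counts_including_reference_panel(self, natural_tables, all_panels,
                                              reference_table):
        a = infer(natural_tables + [reference_table], all_panels)
        assert (a.n_a, a.n_b) == (12, 10)

    def test_single_panel_alone(self, all_panels):
        p = next(x for x in all_panels if x.isolate == "M-8")
        genos = dict(zip(p.testers, p.genotypes))
        a = infer(predict_table(genos, genos), [p])
        assert (a.n_a, a.n_b) == (2, 2)

    def test_soundness_on_fixtures(self, natural_tables, all_panels):
        """Predicting from the inferred genotypes reproduces every scored cell."""
        a = infer(natural_tables, all_panels, exclude=["M-38"])
        pred = predict_table(a.genotypes(), a.genotypes())
        for t in natural_tables:
            for i, r in enumerate(t.row_labels):
                for j, c in enumerate(t.col_labels):
                    v = t.entries[i][j]
                    if v is not Cell.MISSING:
                        assert pred.get(r, c) is v, (r, c)


class TestOracle:
    def test_single_panel(self, all_panels):
        p = next(x for x in all_panels if x.isolate == "M-8")
        genos = dict(zip(p.testers, p.genotypes))
        cs = build_constraints(predict_table(genos, genos), [p])
        assert brute_force_oracle(cs) == (2, 2)

    def test_two_fully_compatible_panels(self):
        p1 = panel("P", ("A1B1", "A1B2", "A2B1", "A2B2"))
        p2 = panel("Q", ("A3B3", "A3B4", "A4B3", "A4B4"))
        genos = dict(zip(p1.testers, p1.genotypes)) | dict(zip(p2.testers,
                                                               p2.genotypes))
        cs = build_constraints(predict_table(genos, genos), [p1, p2])
        assert brute_force_oracle(cs) == (4, 4)

    def test_shared_b_panels(self):
        """Two panels sharing both matB alleles: 4 matA, 2 matB classes."""
        p1 = panel("P", ("A1B1", "A1B2", "A2B1", "A2B2"))
        p2 = panel("Q", ("A3B1", "A3B2", "A4B1", "A4B2"))
        genos = dict(zip(p1.testers, p1.genotypes)) | dict(zip(p2.testers,
                                                               p2.genotypes))
        cs = build_constraints(predict_table(genos, genos), [p1, p2])
        assert brute_force_oracle(cs) == (4, 2)

    def test_refuses_large_instances(self):
        rng = np.random.default_rng(0)
        table, _ = random_instance(rng, max_monokaryons=12)
        cs = build_constraints(table)
        if cs.n <= 12:
            brute_force_oracle(cs)  # fine
        with pytest.raises(ValueError, match="exceeds"):
            brute_force_oracle(cs, max_monokaryons=cs.n - 1)


class TestProperties:
    def test_minimal_assignment_matches_oracle(self):
        """Exact solver equals exhaustive enumeration on 200 random instances."""
        rng = np.random.default_rng(42)
        for k in range(200):
            table, _ = random_instance(rng, max_monokaryons=10,
                                       mask_rate=float(rng.random() * 0.3))
            cs = build_constraints(table)
            a = minimal_assignment(propagate(cs))
            assert (a.n_a, a.n_b) == brute_force_oracle(cs), f"instance {k}"

    def test_recovery_of_true_allele_counts(self):
        """Fully crossed tester panels recover exactly the alleles present.

        Complete panels are what pins every allele down: each A-class
        appears with both of its panel's B alleles, so any two distinct
        A-classes meet in at least one fully heteroallelic (PLUS) cross.
        Isolated monokaryons would not guarantee this.
        """
        from tetramate.simulate import PopulationConfig, simulate_population
        rng = np.random.default_rng(17)
        for _ in range(15):
            cfg = PopulationConfig(
                n_a_pool=int(rng.integers(2, 7)),
                n_b_pool=int(rng.integers(2, 7)),
                n_isolates=int(rng.integers(1, 5)),
                seed=int(rng.integers(2**31)))
            sim = simulate_population(cfg)
            a = infer(sim.monmon, sim.panels)
            assert (a.n_a, a.n_b) == (sim.n_a_true, sim.n_b_true)

    def test_masking_cells_never_increases_counts(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            table, _ = random_instance(rng, max_monokaryons=9)
            full = infer(table)
            masked, _ = table, None
            t2 = CrossTable(table.row_labels, table.col_labels,
                            [[c if rng.random() > 0.4 else Cell.MISSING
                              for c in row] for row in table.entries])
            part = infer(t2)
            assert part.n_a <= full.n_a
            assert part.n_b <= full.n_b

    def test_soundness_on_random_instances(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            table, _ = random_instance(rng, max_monokaryons=9,
                                       mask_rate=float(rng.random() * 0.4))
            a = infer(table)
            pred = predict_table(a.genotypes(), a.genotypes())
            for i, r in enumerate(table.row_labels):
                for j, c in enumerate(table.col_labels):
                    v = table.entries[i][j]
                    if v is not Cell.MISSING and r != c:
                        assert pred.get(r, c) is v


class TestDimonConsistency:
    def setup_method(self):
        genos = ("A1B1", "A1B2", "A2B1", "A2B2")
        self.testers = {f"m{i + 1}": parse_genotype(s)
                        for i, s in enumerate(genos)}

    def _report(self, row):
        t = CrossTable(["D"], list(self.testers),
                       [[{"+": Cell.PLUS, "-": Cell.MINUS}[x] for x in row]],
                       [RowKind.DIKARYON])
        return check_dimon_consistency(t, self.testers)[0]

    def test_all_plus_row_does_not_force_novel_alleles(self):
        """An all-compatible row is explainable without any new allele...

        e.g. by a dikaryon novel at matB only -- so novelty at matA is not
        forced, matching exhaustive enumeration.
        """
        r = self._report("++++")
        assert r.satisfiable
        assert not r.forced_novel_a and not r.forced_novel_b

    def test_cis_pattern_row_satisfiable(self):
        r = self._report("+--+")
        assert r.satisfiable
        assert "A1B1+A2B2" in r.examples

    def test_all_minus_row_unsatisfiable(self):
        r = self._report("----")
        assert not r.satisfiable
        assert r.n_satisfying == 0

    def test_never_claims_forced_novelty_against_a_counterexample(self):
        """Ground-truth dikaryons built from observed alleles must never be
        reported as requiring a novel allele."""
        rng = np.random.default_rng(31)
        genos = list(self.testers.values())
        for _ in range(50):
            i, j = rng.choice(len(genos), size=2)
            if genos[i].a == genos[j].a or genos[i].b == genos[j].b:
                continue
            d = Dikaryon(genos[i], genos[j])
            t = predict_table({"D": d}, self.testers)
            r = check_dimon_consistency(t, self.testers)[0]
            assert r.satisfiable
            assert not r.forced_novel_a and not r.forced_novel_b

    def test_bundled_dimon_rows_all_consistent(self, all_panels):
        ref = next(p for p in all_panels if p.isolate == "M-38")
        reports = check_dimon_consistency(
            fixtures.load_dimon_crosses(),
            dict(zip(ref.testers, ref.genotypes)))
        assert len(reports) == 12
        assert all(r.satisfiable for r in reports)
        assert not any(r.forced_novel_a or r.forced_novel_b for r in reports)
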