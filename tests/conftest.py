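import numpy as np
import pytest

from tetramate import fixtures
from tetramate.mating import AlleleLabel, MatingGenotype
from tetramate.tables import Cell, CrossTable, predict_table


def random_genotypes(rng, n, n_a_pool, n_b_pool, prefix="m"):
    """Random monokaryon genotypes drawn from finite allele pools."""
    out = {}
    for k in range(n):
        a = AlleleLabel("A", f"A{rng.integers(1, n_a_pool + 1)}")
        b = AlleleLabel("B", f"B{rng.integers(1, n_b_pool + 1)}")
        out[f"{prefix}{k + 1}"] = MatingGenotype(a, b)
    return out


def random_instance(rng, max_monokaryons=12, mask_rate=0.0):
    """A satisfiable random inference instance: genotype-derived cross table.

    Returns (table, genotypes).  Derived from real genotypes, so a
    consistent assignment always exists.
    """
    n = int(rng.integers(3, max_monokaryons + 1))
    pool_a = int(rng.integers(2, 6))
    pool_b = int(rng.integers(2, 6))
    genos = random_genotypes(rng, n, pool_a, pool_b)
    table = predict_table(genos, genos)
    if mask_rate > 0:
        for i in range(n):
            for j in range(n):
                if rng.random() < mask_rate:
                    table.entries[i][j] = Cell.MISSING
    return table, genos


@pytest.fixture(scope="session")
def natural_tables():
    return [fixtures.load_natural_crosses(), fixtures.load_stated_crosses()]


@pytest.fixture(scope="session")
def all_panels():
    return fixtures.load_panels()


@pytest.fixture(scope="session")
def reference_table():
    return fixtures.load_monmon_vs_reference()
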