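import numpy as np
import pytest

from gbas.io import AlleleLabel, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(cells, loci=None):
    """Build a GenotypeMatrix from {(sample, pop): {locus: (len_a, len_b)|None}}."""
    individuals = list(cells.keys())
    all_loci = loci or sorted({l for row in cells.values() for l in row})
    calls = {}
    for (sample, _pop), row in cells.items():
        for locus, pair in row.items():
            if pair is None:
                continue
            a, b = pair
            calls[(sample, locus)] = tuple(
                sorted((AlleleLabel(a), AlleleLabel(b)))
            )
    return GenotypeMatrix(individuals, all_loci, calls)


@pytest.fixture
def two_pop_matrix():
    """Two populations of 4, one locus fixed for different alleles plus one
    shared polymorphic locus."""
    cells = {}
    for i in range(4):
        cells[(f"a{i}", "A")] = {"L1": (100, 100), "L2": (200, 204)}
        cells[(f"b{i}", "B")] = {"L1": (104, 104), "L2": (200, 204)}
    return make_matrix(cells)
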