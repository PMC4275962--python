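import itertools

import numpy as np
import pytest

from ibvs import GeneNetwork, GenotypeData, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_geno(rng):
    """6 samples x 4 SNPs in 2 genes, with some within-gene correlation."""
    X = rng.integers(0, 3, (6, 4))
    X[:, 1] = np.clip(X[:, 0] + rng.integers(0, 2, 6), 0, 2)
    return GenotypeData(X, [f"s{i}" for i in range(6)],
                        [f"snp{k}" for k in range(4)],
                        np.array([0, 0, 1, 1]), ["gA", "gB"])


@pytest.fixture
def toy_y():
    return Phenotype(np.array([1, 1, 1, 0, 0, 0]))


@pytest.fixture
def toy_net():
    return GeneNetwork(np.array([[0, 1], [1, 0]]), ["gA", "gB"])


def consistent_models_2x2():
    """All 16 consistent (xi, gamma) states for 2 genes with 2 SNPs each."""
    per_gene = [(0, (0, 0)), (1, (1, 0)), (1, (0, 1)), (1, (1, 1))]
    for (x1, g1), (x2, g2) in itertools.product(per_gene, per_gene):
        yield np.array([x1, x2]), np.array(list(g1) + list(g2))
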