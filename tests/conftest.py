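import numpy as np
import pytest

from pcsnp.genotype_io import GenotypeMatrix, impute_mode
from pcsnp.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """Imputed tiny simulation: 3 breeds x 10 samples, 60 SNPs, 6 planted."""
    G, truth = make_fixture("tiny")
    return impute_mode(G), truth


@pytest.fixture(scope="session")
def null_data():
    """No informative SNPs; accuracies should sit at chance."""
    G, truth = make_fixture("null")
    return G, truth


@pytest.fixture()
def toy_matrix():
    """Hand-built 2-breed matrix: SNP 'sep' perfectly separates the breeds."""
    rng = np.random.default_rng(5)
    m = 24
    labels = ["A"] * 12 + ["B"] * 12
    sep = np.array([0] * 12 + [2] * 12)
    noise = rng.integers(0, 3, size=(m, 8))
    values = np.column_stack([sep, noise])
    ids = ["sep"] + [f"noise{i}" for i in range(8)]
    return GenotypeMatrix(values, [f"s{i}" for i in range(m)], ids, labels)
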