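import numpy as np
import pandas as pd
import pytest

from eelkit.codebook import assign_genes, generate_codebook


@pytest.fixture(scope="session")
def full_codebook():
    """The complete deterministic 16/6/4 construction (504 codewords)."""
    return generate_codebook(16, 6, 4)


@pytest.fixture(scope="session")
def codebook448():
    """The 448-codeword channel codebook actually used per color."""
    return generate_codebook(16, 6, 4, size=448)


@pytest.fixture(scope="session")
def assigned_book(codebook448):
    """448-word codebook with 20 genes assigned; the rest are blanks."""
    genes = [f"Gene{i:03d}" for i in range(20)]
    _, book = assign_genes(codebook448, genes)
    return book


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture()
def uniform_molecules(rng):
    """20k molecules of 10 genes uniform over a 1 mm square."""
    n = 20000
    return pd.DataFrame(
        {
            "gene": rng.choice([f"G{i}" for i in range(10)], size=n),
            "x_um": rng.uniform(0, 1000, n),
            "y_um": rng.uniform(0, 1000, n),
        }
    )
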