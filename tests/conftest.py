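import numpy as np
import pandas as pd
import pytest

from stromasig import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_matrix(rng):
    """A 50-gene, 12-sample matrix of plain Gaussian log2 intensities."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"s{j:02d}" for j in range(12)]
    values = rng.normal(8.0, 1.0, size=(50, 12))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_matrix(values, gene_prefix="G", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i + 1}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
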