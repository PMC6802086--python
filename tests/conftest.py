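import numpy as np
import pandas as pd
import pytest

from ctcpanel import ExpressionMatrix, GeneratorConfig


@pytest.fixture
def small_config():
    """A scaled-down generator config for fast unit tests."""
    return GeneratorConfig(
        n_genes=300,
        n_tumor=60,
        n_cell_line=12,
        n_blood=60,
        n_pbmc=8,
        n_datasets=5,
        samples_per_dataset=6,
        seed=7,
    )


@pytest.fixture
def random_matrix():
    """Factory for random linear-scale expression matrices."""

    def make(n_genes=50, n_samples=20, seed=0, scale="linear"):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 1000.0, size=(n_genes, n_samples))
        if scale == "log2":
            values = np.log2(values)
        df = pd.DataFrame(
            values,
            index=[f"PS{i:05d}" for i in range(n_genes)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        )
        return ExpressionMatrix(df, scale=scale)

    return make
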