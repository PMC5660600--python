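import numpy as np
import pandas as pd
import pytest

from cnvatten import OmicsMatrix, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene, 120-sample cohort with 8 complexes; fast to analyse."""
    return simulate_dataset(
        SimulationConfig(n_samples=120, n_genes=300, n_complexes=8, seed=7)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full default cohort (282 samples, 2,000 genes, 30 complexes)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def as_omics(arr, level, prefix="G"):
    arr = np.asarray(arr, dtype=float)
    genes = [f"{prefix}{i:04d}" for i in range(arr.shape[0])]
    samples = [f"S{j:04d}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=genes, columns=samples), level)
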