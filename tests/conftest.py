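import numpy as np
import pandas as pd
import pytest

from cardiomembrane.synthetic import GeneratorConfig, generate_dataset
from cardiomembrane.types import SpectralCountTable


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by read-only tests."""
    config = GeneratorConfig(n_proteins=80, seed=11)
    return generate_dataset(config)


def make_count_table(rows: dict, n_reps: int = 3) -> SpectralCountTable:
    """Build a toy count table from {protein: [mem..., hom...]} lists."""
    cols = [f"m{r}" for r in range(1, n_reps + 1)] + [
        f"h{r}" for r in range(1, n_reps + 1)
    ]
    meta = pd.DataFrame(
        {
            "fraction": ["membrane"] * n_reps + ["homogenate"] * n_reps,
            "replicate": list(range(1, n_reps + 1)) * 2,
        },
        index=cols,
    )
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return SpectralCountTable(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
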