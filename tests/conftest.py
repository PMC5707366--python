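import numpy as np
import pandas as pd
import pytest

from cytocross import synthetic
from cytocross.stats import CountMatrix


@pytest.fixture(scope="session")
def demo_dataset():
    """Small full synthetic dataset shared across the suite."""
    return synthetic.make_dataset(synthetic.demo_config(), seed=7)


@pytest.fixture(scope="session")
def demo_truth(demo_dataset):
    return demo_dataset.truth


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix: 4 genes x 2 conditions x 2 reps."""
    counts = pd.DataFrame(
        {
            "A_1": [10, 100, 0, 50],
            "A_2": [12, 90, 0, 55],
            "B_1": [20, 95, 0, 48],
            "B_2": [22, 105, 0, 52],
        },
        index=pd.Index([f"g{i}" for i in range(4)], name="feature"),
    )
    cond = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1500.0], index=counts.index)
    return CountMatrix(counts, cond, lengths)


def nb_counts(rng, mean, alpha, size):
    """Reference NB sampler used by oracles (mean/dispersion form)."""
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)
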