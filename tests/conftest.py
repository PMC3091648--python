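import warnings

import numpy as np
import pandas as pd
import pytest

from tfnet import SyntheticConfig
from tfnet.containers import ExpressionDataset


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_two_group_dataset(
    mutant: np.ndarray, control: np.ndarray, genes=None, present=None
) -> ExpressionDataset:
    """One-experiment dataset from explicit per-group value blocks."""
    mutant = np.atleast_2d(np.asarray(mutant, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_genes = mutant.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols = [f"E01_mut_{i}" for i in range(mutant.shape[1])] + [
        f"E01_con_{i}" for i in range(control.shape[1])
    ]
    values = pd.DataFrame(np.hstack([mutant, control]), index=genes, columns=cols)
    design = pd.DataFrame(
        {
            "experiment": "E01",
            "group": ["mutant"] * mutant.shape[1] + ["control"] * control.shape[1],
        },
        index=cols,
    )
    if present is None:
        present_df = pd.DataFrame(True, index=genes, columns=cols)
    else:
        present_df = pd.DataFrame(present, index=genes, columns=cols)
    return ExpressionDataset(values=values, design=design, present=present_df)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Twenty seeded end-to-end runs at the default synthetic config.

    Shared across the recovery-oriented tests so the pipeline only runs
    once per session.
    """
    from tfnet import run_synthetic_benchmark

    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 21):
            runs.append(run_synthetic_benchmark(SyntheticConfig(seed=seed)))
    return runs
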