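import numpy as np
import pandas as pd
import pytest

from decombine import CountMatrix, SampleSheet, SimConfig, simulate_dataset


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(values)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def make_sheet(n1: int, n2: int, samples=None) -> SampleSheet:
    samples = samples or [f"s{i + 1}" for i in range(n1 + n2)]
    return SampleSheet(
        pd.DataFrame({"condition": ["a"] * n1 + ["b"] * n2}, index=samples),
        condition_col="condition",
        ref_level="a",
        test_level="b",
    )


@pytest.fixture(scope="session")
def small_null_dataset():
    """Preset-1 style null dataset, scaled down for unit tests."""
    cfg = SimConfig.from_preset(1, n_per_group=10, seed=11, n_genes=2000)
    return simulate_dataset(cfg, 0)


@pytest.fixture(scope="session")
def small_de_dataset():
    """Balanced-DE dataset (preset 2 style), scaled down."""
    cfg = SimConfig.from_preset(2, n_per_group=3, seed=11, n_genes=2000)
    return simulate_dataset(cfg, 0)
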