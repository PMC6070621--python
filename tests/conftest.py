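import numpy as np
import pandas as pd
import pytest

from nbmm import LongitudinalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20180726)


def make_dataset(counts: dict, subjects, times, total_reads=None, **covariates):
    """Small long-format dataset from plain lists (test helper)."""
    n = len(subjects)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
    counts_df = pd.DataFrame(counts, index=idx, dtype=np.int64)
    if total_reads is None:
        total_reads = counts_df.sum(axis=1).to_numpy()
    samples = pd.DataFrame(
        {"subject": subjects, "time": times, "total_reads": total_reads, **covariates},
        index=idx,
    )
    return LongitudinalDataset(samples, counts_df)


@pytest.fixture
def toy_dataset():
    """2 taxa x 6 samples, 3 subjects x 2 time points, binary group."""
    return make_dataset(
        {"taxA": [3, 1, 0, 5, 2, 4], "taxB": [0, 2, 5, 0, 1, 1]},
        subjects=["a", "a", "b", "b", "c", "c"],
        times=[0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        total_reads=[10, 12, 9, 15, 11, 14],
        group=[1, 1, 0, 0, 1, 1],
    )
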