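import numpy as np
import pytest

from bivbin.dataset import BivariateBinaryDataset


@pytest.fixture
def reconstructed_outcomes():
    """Outcome vectors whose 2x2 table is [[14, 207], [8, 34]].

    Rows: 221 subjects with the first endpoint (14 of whom also have the
    second) and 42 without it (8 with the second) — the printed cohort
    margins.
    """
    y1 = np.r_[np.ones(221), np.zeros(42)]
    y2 = np.r_[np.ones(14), np.zeros(207), np.ones(8), np.zeros(34)]
    return y1.astype(int), y2.astype(int)


@pytest.fixture
def separable_toy():
    """A noiseless, linearly separable bivariate task (40 rows, 2 covariates)."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(40, 2))
    y1 = (X[:, 0] > 0).astype(int)
    y2 = (X[:, 1] > 0).astype(int)
    return BivariateBinaryDataset(X, y1, y2)


@pytest.fixture
def random_dataset():
    """Small random dataset for oracle comparisons (12 rows, 3 covariates)."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 3))
    return BivariateBinaryDataset(X, rng.integers(0, 2, 12), rng.integers(0, 2, 12))
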