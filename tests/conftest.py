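import numpy as np
import pytest

from chromclust import ChromatinDataset, default_alpha_fixtures, simulate_dmm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 loci x 2 features x 4 bins with hand-written counts."""
    f1 = np.array([[3, 0, 1, 0], [0, 2, 2, 1], [1, 1, 0, 3]])
    f2 = np.array([[0, 4, 0, 0], [1, 0, 3, 0], [2, 2, 0, 0]])
    return ChromatinDataset(counts=[f1, f2], feature_names=["a", "b"])


@pytest.fixture
def two_cluster_dataset():
    """Well-separated two-cluster draw from the model, coverage 100."""
    alpha = default_alpha_fixtures(30, 2)
    return simulate_dmm(alpha, [0.5, 0.5], [100, 100], 200, seed=42, bin_size=40)
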