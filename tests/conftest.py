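import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oplshda import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(X, labels, prefix="s"):
    """Wrap raw arrays in a Dataset with generated ids/names."""
    X = np.asarray(X, dtype=float)
    return Dataset(
        values=X,
        sample_ids=[f"{prefix}{i}" for i in range(X.shape[0])],
        variable_names=[f"v{j}" for j in range(X.shape[1])],
        labels=list(labels),
    )


@pytest.fixture
def two_blob_dataset(rng):
    """Two well-separated Gaussian classes on one informative variable."""
    n = 14
    X = rng.normal(size=(2 * n, 5)) * 0.3
    X[:n, 0] += 0.0
    X[n:, 0] += 6.0
    return make_dataset(X, ["low"] * n + ["high"] * n)
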