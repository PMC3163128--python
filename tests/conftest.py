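import numpy as np
import pytest

from nmfdl.core import DataField


@pytest.fixture
def two_cluster_1d():
    """50 scalar samples from two unit-variance clusters 8 sigma apart."""
    rng = np.random.default_rng(42)
    X = np.concatenate([rng.normal(0.0, 1.0, (25, 1)), rng.normal(8.0, 1.0, (25, 1))])
    return DataField(X)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
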