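import numpy as np
import pytest

from lupine.quantio import QuantMatrix


def make_qm(values, prefix_p="P", prefix_s="S", dataset=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return QuantMatrix(
        values,
        [f"{prefix_p}{i}" for i in range(n)],
        [f"{prefix_s}{j}" for j in range(m)],
        [dataset] * m if dataset else None,
    )


@pytest.fixture
def gaussian_qm():
    """200 x 50 standard-normal matrix, fully observed."""
    rng = np.random.default_rng(123)
    return make_qm(rng.normal(0, 1, (200, 50)))


@pytest.fixture
def rank1_qm():
    """100 x 20 additive (rank-1-plus-noise) matrix on a log-intensity scale."""
    rng = np.random.default_rng(42)
    u = rng.normal(6, 1, 100)
    v = rng.normal(6, 1, 20)
    X = u[:, None] + v[None, :] + rng.normal(0, 0.1, (100, 20))
    return make_qm(X)
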