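import logging

import numpy as np
import pytest

from specgc import (
    FrequencyGrid,
    make_three_node_benchmark,
    make_two_node_benchmark,
    make_var,
)

# clamp warnings are expected in the misspecified-estimator studies; keep
# test output readable
logging.getLogger("specgc").setLevel(logging.ERROR)

RECEIVER_FREQS = (10.0, 30.0, 50.0)


@pytest.fixture(scope="session")
def three_node():
    return make_three_node_benchmark()


@pytest.fixture(scope="session")
def two_node_models():
    return {f: make_two_node_benchmark(f) for f in RECEIVER_FREQS}


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.default(120.0)


def ordered_pairs(model):
    """All ordered channel pairs, each conditioned on the remaining channels."""
    labels = model.channel_labels
    out = []
    for s in labels:
        for t in labels:
            if s == t:
                continue
            out.append((s, t, tuple(c for c in labels if c not in (s, t))))
    return out


def random_stable_var(rng, n_channels=3, order=2, radius=None, diagonal_sigma=True):
    """Draw a random VAR with companion spectral radius scaled to ``radius``
    (default uniform in [0.5, 0.9]); innovation variances uniform in [0.5, 2]."""
    from specgc.var_models import companion_matrix

    if radius is None:
        radius = rng.uniform(0.5, 0.9)
    coeffs = rng.normal(scale=0.5, size=(order, n_channels, n_channels))
    rho = np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs))))
    if rho > 0:
        gamma = radius / rho
        for k in range(order):
            coeffs[k] *= gamma ** (k + 1)
    if diagonal_sigma:
        sigma = np.diag(rng.uniform(0.5, 2.0, size=n_channels))
    else:
        a = rng.normal(size=(n_channels, n_channels))
        sigma = a @ a.T + n_channels * np.eye(n_channels)
    return make_var(coeffs, sigma, fs=120.0)
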