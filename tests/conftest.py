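import numpy as np
import pytest

from connectoflux.matrices import (
    ConnectivityMatrix,
    ThresholdSpec,
    ThresholdedNetwork,
    apply_threshold,
    compute_threshold,
)


def make_matrix(weights, subject_id="test") -> ConnectivityMatrix:
    """Build a ConnectivityMatrix from an upper-triangle-consistent array."""
    w = np.asarray(weights, dtype=float)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(subject_id=subject_id, weights=w)


def make_net(weights, w_t: float) -> ThresholdedNetwork:
    """Thresholded network from explicit weights and an explicit cut-off."""
    m = make_matrix(weights)
    spec = ThresholdSpec(n=0.0, mean_abs_w=w_t, sd_abs_w=0.0)
    return apply_threshold(m, spec)


def random_symmetric(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    w[iu] = rng.uniform(-1, 1, size=iu[0].size)
    w += w.T
    return ConnectivityMatrix(subject_id="rand", weights=w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    # 4-node matrix with distinct off-diagonal magnitudes
    return make_matrix(
        [
            [0.0, 0.1, 0.2, 0.3],
            [0.1, 0.0, -0.6, 0.15],
            [0.2, -0.6, 0.0, 0.25],
            [0.3, 0.15, 0.25, 0.0],
        ]
    )


def net_with_explicit_threshold(weights, w_t: float) -> ThresholdedNetwork:
    """Network whose retained weights are given directly; w_t only sets the
    response classification band (no re-thresholding of the weights)."""
    w = np.asarray(weights, dtype=float)
    adj = (w != 0).astype(np.int8)
    return ThresholdedNetwork(
        spec=ThresholdSpec(n=0.0, mean_abs_w=w_t, sd_abs_w=0.0),
        weights=w,
        adjacency=adj,
    )


@pytest.fixture
def three_node_net():
    # retained weights w~_12 = 0.6, w~_13 = -0.5, w~_23 = 0.3; band w_t = 0.4
    w = np.array(
        [
            [0.0, 0.6, -0.5],
            [0.6, 0.0, 0.3],
            [-0.5, 0.3, 0.0],
        ]
    )
    return net_with_explicit_threshold(w, w_t=0.4)
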