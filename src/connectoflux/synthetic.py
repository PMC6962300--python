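"""Synthetic connectivity matrices and strength samples.

Three generators cover everything the analysis pipeline consumes:

* uniform-weight null matrices — the random baseline ensemble (i.i.d.
  weights on [-1, 1], symmetric, zero diagonal);
* factor-model correlation matrices — brain-like inputs with a global
  signal, community structure and hub nodes, giving right-skewed node
  strengths;
* direct draws from the upper-truncated power-law strength density
  p(ns) ~ (ns_max - ns)^gamma, for estimator-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from connectoflux.matrices import ConnectivityMatrix

__all__ = [
    "NullModelParams",
    "FactorModelParams",
    "random_null_matrices",
    "iter_null_matrices",
    "factor_model_matrix",
    "sample_strengths",
]


@dataclass(frozen=True)
class NullModelParams:
    """Ensemble of symmetric matrices with i.i.d. uniform [-1, 1] weights."""

    N: int = 177
    count: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class FactorModelParams:
    """Latent-factor time-series model producing hub/community correlations.

    Node i's series is ``x_i(t) = a_i g(t) + b_i f_c(i)(t) + eps_i(t)`` with a
    standard-normal global signal g shared by a random ``hub_fraction`` of
    nodes (loading ``hub_loading``), one community signal per block (loading
    ``community_loading``) and i.i.d. Gaussian noise.  The Pearson correlation
    matrix of the series has elevated strength at hubs, so the node-strength
    distribution is right-skewed like empirical connectomes.
    """

    N: int = 120
    T: int = 200
    n_communities: int = 4
    hub_fraction: float = 0.10
    hub_loading: float = 0.8
    community_loading: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 10:
            raise ValueError("need at least 10 time points")
        if not 1 <= self.n_communities <= self.N:
            raise ValueError("n_communities must be in [1, N]")
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValueError("hub_fraction must be in (0, 1)")
        if int(self.hub_fraction * self.N) < 1:
            raise ValueError("hub_fraction * N must be at least 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def random_null_matrices(params: NullModelParams) -> list[ConnectivityMatrix]:
    """Generate the null ensemble; deterministic per (seed, index).

    Each matrix draws its upper triangle i.i.d. uniform on [-1, 1], mirrors
    it, and zeroes the diagonal.  Matrix ``k`` uses an independent stream
    keyed by (seed, k) so subsets of the ensemble are reproducible.
    """
    return [
        _null_matrix(params.N, params.seed, k) for k in range(params.count)
    ]


def iter_null_matrices(params: NullModelParams):
    """Lazy variant of :func:`random_null_matrices` for large ensembles."""
    for k in range(params.count):
        yield _null_matrix(params.N, params.seed, k)


def _null_matrix(n: int, seed: int, index: int) -> ConnectivityMatrix:
    rng = np.random.default_rng([seed, index])
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = rng.uniform(-1.0, 1.0, size=iu[0].size)
    w += w.T
    return ConnectivityMatrix(subject_id=f"null_{index:04d}", weights=w)


def factor_model_matrix(params: FactorModelParams) -> ConnectivityMatrix:
    """Simulate the factor model and return its Pearson correlation matrix."""
    rng = np.random.default_rng(params.seed)
    N, T = params.N, params.T

    g = rng.standard_normal(T)
    communities = np.arange(N) % params.n_communities
    f = rng.standard_normal((params.n_communities, T))
    eps = rng.standard_normal((N, T)) * params.noise_sd

    n_hubs = max(1, int(round(params.hub_fraction * N)))
    hubs = rng.choice(N, size=n_hubs, replace=False)
    a = np.zeros(N)
    a[hubs] = params.hub_loading

    x = a[:, None] * g[None, :] + params.community_loading * f[communities] + eps
    w = np.corrcoef(x)
    np.fill_diagonal(w, 0.0)
    # corrcoef can leave ~1e-16 asymmetry; the container requires 1e-9
    w = (w + w.T) / 2.0
    return ConnectivityMatrix(subject_id=f"factor_{params.seed}", weights=w)


def sample_strengths(
    gamma: float,
    ns_max: float,
    ns_min: float,
    n: int,
    seed: int,
) -> npt.NDArray[np.float64]:
    """Draw i.i.d. samples from p(ns) ~ (ns_max - ns)^gamma on [ns_min, ns_max].

    In the mirrored variable u = ns_max - ns this is the power-function law
    with CDF (u / u_max)^(gamma+1), sampled by inversion: u = u_max *
    v^(1/(gamma+1)) for v ~ U(0, 1).  Requires gamma > -1 for normalizability.
    """
    if gamma <= -1.0:
        raise ValueError("gamma must exceed -1 for a normalizable density")
    if not ns_min < ns_max:
        raise ValueError("ns_min must be strictly below ns_max")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    u_max = ns_max - ns_min
    u = u_max * rng.uniform(size=n) ** (1.0 / (gamma + 1.0))
    return ns_max - u
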