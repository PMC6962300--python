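"""Topological and node-strength characterization of thresholded networks.

Covers the structural side of the threshold sweep: fraction of nodes in the
largest connected component (the percolation indicator), global clustering
(transitivity), its consecutive differences along a threshold series, and
node strengths ns_i = sum_j |w~_ij| together with the upper-truncated
power-law model

    p(ns) ~ (ns_max - ns)^gamma,   ns in [ns_min, ns_max],

fitted by conditional maximum likelihood with the truncation point chosen by
Kolmogorov-Smirnov minimization, plus a normal-model KS distance on the same
sample for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import numpy.typing as npt
from scipy import sparse, stats

from connectoflux.matrices import ThresholdedNetwork

__all__ = [
    "TopologySummary",
    "StrengthDistributionFit",
    "ClusteringSeries",
    "largest_component_fraction",
    "clustering_coefficient",
    "clustering_differences",
    "node_strengths",
    "truncated_power_cdf",
    "fit_strength_model",
    "ks_distance",
]

_GRID_SIZE_DEFAULT = 50


@dataclass(frozen=True)
class TopologySummary:
    """Largest-component fraction and global clustering of one network."""

    lcc_fraction: float
    clustering: float


@dataclass(frozen=True)
class StrengthDistributionFit:
    """Fitted (gamma, ns_max) with KS distances of the model and a normal fit."""

    gamma: float
    ns_max: float
    ns_min: float
    ks_D: float
    ks_D_normal: float


@dataclass(frozen=True)
class ClusteringSeries:
    """Clustering coefficients along an ascending threshold grid."""

    thresholds: npt.NDArray[np.float64]
    C_values: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        c = np.asarray(self.C_values, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("thresholds and C_values must be matching vectors")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "C_values", c)


def largest_component_fraction(net: ThresholdedNetwork) -> float:
    """Size of the largest connected component divided by N.

    Isolated nodes count as components of size one, so the value is at
    least 1/N.
    """
    adj = sparse.csr_matrix(net.adjacency)
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return float(sizes.max() / net.n_nodes)


def clustering_coefficient(net: ThresholdedNetwork) -> float:
    """Global transitivity: 3 * triangles / connected triples (0 if no triples)."""
    g = nx.from_numpy_array(net.adjacency)
    return float(nx.transitivity(g))


def clustering_differences(series: ClusteringSeries) -> npt.NDArray[np.float64]:
    """Consecutive drops Delta_C(i) = C(i) - C(i+1), low-threshold side first."""
    if series.C_values.size < 2:
        raise ValueError("need at least two points to difference")
    return series.C_values[:-1] - series.C_values[1:]


def node_strengths(net: ThresholdedNetwork) -> npt.NDArray[np.float64]:
    """Absolute node strengths ns_i = sum_j |w~_ij| on the thresholded weights."""
    return np.abs(net.weights).sum(axis=1)


def truncated_power_cdf(
    x: npt.NDArray, gamma: float, ns_max: float, ns_min: float
) -> npt.NDArray[np.float64]:
    """CDF of p(ns) ~ (ns_max - ns)^gamma on [ns_min, ns_max]."""
    x = np.asarray(x, dtype=float)
    u_max = ns_max - ns_min
    frac = np.clip((ns_max - x) / u_max, 0.0, 1.0)
    return 1.0 - frac ** (gamma + 1.0)


def ks_distance(
    sorted_sample: npt.NDArray, model_cdf: Callable[[npt.NDArray], npt.NDArray]
) -> float:
    """Two-sided KS statistic between an empirical sample and a model CDF.

    D = max_k max(|F(x_(k)) - k/n|, |F(x_(k)) - (k-1)/n|) over the sorted
    sample — the exact supremum of the step-function gap.
    """
    x = np.asarray(sorted_sample, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("sample must be a non-empty vector")
    if np.any(np.diff(x) < 0):
        raise ValueError("sample must be sorted ascending")
    n = x.size
    f = np.asarray(model_cdf(x), dtype=float)
    k = np.arange(1, n + 1)
    return float(
        np.max(np.maximum(np.abs(f - k / n), np.abs(f - (k - 1) / n)))
    )


def _gamma_mle(ns: npt.NDArray, ns_max: float, ns_min: float) -> float:
    # conditional MLE for the exponent given the truncation point:
    # gamma + 1 = 1 / mean(ln((ns_max - ns_min) / (ns_max - ns_i)))
    logs = np.log((ns_max - ns_min) / (ns_max - ns))
    mean_log = logs.mean()
    if mean_log <= 0:
        return np.inf
    return 1.0 / mean_log - 1.0


def fit_strength_model(
    ns: Sequence[float] | npt.NDArray,
    grid_size: int = _GRID_SIZE_DEFAULT,
) -> StrengthDistributionFit:
    """Fit the upper-truncated power law to a strength sample.

    For each candidate truncation point ns_max on a ``grid_size``-point grid
    just above max(ns) and up to max(ns) + 2 * range(ns), the exponent gamma
    has a closed-form conditional MLE; the candidate minimizing the KS
    distance between the model CDF and the empirical CDF wins.  The lower
    support bound is fixed at min(ns).  A mean/sd normal fit to the same
    sample provides the comparison KS distance.
    """
    x = np.sort(np.asarray(ns, dtype=float))
    if x.size < 10:
        raise ValueError("need at least 10 strengths to fit")
    ns_min, obs_max = float(x[0]), float(x[-1])
    rng_width = obs_max - ns_min
    if rng_width <= 0:
        raise ValueError("degenerate sample: all strengths equal")
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")

    candidates = np.linspace(
        obs_max * (1.0 + 1e-6) if obs_max > 0 else obs_max + 1e-6 * rng_width,
        obs_max + 2.0 * rng_width,
        grid_size,
    )
    best: tuple[float, float, float] | None = None  # (D, gamma, ns_max)
    for cand in candidates:
        gamma = _gamma_mle(x, cand, ns_min)
        if not np.isfinite(gamma) or gamma <= -1.0:
            continue
        d = ks_distance(x, lambda v: truncated_power_cdf(v, gamma, cand, ns_min))
        if best is None or d < best[0]:
            best = (d, gamma, cand)
    if best is None:
        raise ValueError("no admissible truncation point found")

    mu, sd = float(x.mean()), float(x.std(ddof=1))
    d_normal = ks_distance(x, lambda v: stats.norm.cdf(v, loc=mu, scale=sd))
    return StrengthDistributionFit(
        gamma=best[1],
        ns_max=best[2],
        ns_min=ns_min,
        ks_D=best[0],
        ks_D_normal=d_normal,
    )
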