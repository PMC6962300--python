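"""Plug-in entropy and mutual-information estimation for ternary states.

Pairwise transfer between a stimulus node i and a response node j is scored
as m(i, j) = H(s_i) + H(r_j) - H(s_i, r_j) in bits, estimated by plugging the
empirical state frequencies over the K repeated stimuli into the entropy
formula (no bias correction; what the repeated-stimulus design measures is
the plug-in value at the chosen K).  The network-level summary averages
m(i, j) over the N - 1 possible sources of each target j and then over all
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from connectoflux.transfer import ResponseBatch, StimulusBatch

__all__ = ["PairJointCounts", "MISummary", "ternary_entropy", "pair_mi", "network_mi"]

_NEG_TOL = -1e-12
_STATES = (-1, 0, 1)


@dataclass(frozen=True)
class PairJointCounts:
    """3x3 joint count table over (s, r) in {-1, 0, +1}^2."""

    counts: npt.NDArray[np.int64]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3):
            raise ValueError("joint counts must be a 3x3 table")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MISummary:
    """Pairwise MI matrix with the node- and network-level averages (bits)."""

    pair_mi: npt.NDArray[np.float64] = field(repr=False)  # N x N, nan diagonal
    node_means: npt.NDArray[np.float64]  # <m(j)> over N-1 sources
    network_mi: float


def _plugin_entropy(p: npt.NDArray[np.float64]) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def ternary_entropy(counts) -> float:
    """Plug-in entropy in bits of a ternary variable from its state counts."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("expected three state counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("entropy undefined for all-zero counts")
    return _plugin_entropy(c / total)


def pair_mi(joint: PairJointCounts | npt.NDArray) -> float:
    """Plug-in mutual information H(s) + H(r) - H(s, r) in bits.

    Tiny negative values from floating-point cancellation are clamped to 0.
    """
    table = joint.counts if isinstance(joint, PairJointCounts) else np.asarray(joint)
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        raise ValueError("joint table must contain at least one observation")
    p = table / total
    mi = (
        _plugin_entropy(p.sum(axis=1))
        + _plugin_entropy(p.sum(axis=0))
        - _plugin_entropy(p.ravel())
    )
    if mi < _NEG_TOL:  # genuine negatives indicate a bug upstream
        raise AssertionError(f"plug-in MI below tolerance: {mi}")
    return max(mi, 0.0)


def _state_indicators(states: npt.NDArray) -> list[npt.NDArray[np.float64]]:
    return [(states == s).astype(float) for s in _STATES]


def network_mi(S: StimulusBatch, R: ResponseBatch) -> MISummary:
    """Pairwise plug-in MI for every ordered (source i, target j), i != j.

    The 3x3 joint tables for all N^2 pairs are accumulated with nine
    indicator-matrix products, so the cost is a handful of K x N matmuls
    rather than an N^2 Python loop.
    """
    if S.K != R.K:
        raise ValueError("stimulus and response batches are not aligned")
    if S.K < 2:
        raise ValueError("need at least 2 samples to estimate MI")
    K, N = S.states.shape
    if R.states.shape != (K, N):
        raise ValueError("stimulus and response shapes differ")

    A = _state_indicators(S.states)  # per stimulus state, K x N
    B = _state_indicators(R.states)  # per response state, K x N

    # marginal entropies per node
    h_s = np.zeros(N)
    h_r = np.zeros(N)
    for a in range(3):
        ps = A[a].sum(axis=0) / K
        pr = B[a].sum(axis=0) / K
        h_s -= np.where(ps > 0, ps * np.log2(np.where(ps > 0, ps, 1.0)), 0.0)
        h_r -= np.where(pr > 0, pr * np.log2(np.where(pr > 0, pr, 1.0)), 0.0)

    # joint entropy per ordered pair
    h_joint = np.zeros((N, N))
    for a in range(3):
        for b in range(3):
            p = (A[a].T @ B[b]) / K
            h_joint -= np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)

    m = h_s[:, None] + h_r[None, :] - h_joint
    if float(m.min()) < _NEG_TOL:
        raise AssertionError("plug-in MI matrix below negative tolerance")
    np.clip(m, 0.0, None, out=m)

    mask = ~np.eye(N, dtype=bool)
    node_means = np.where(mask, m, 0.0).sum(axis=0) / (N - 1)
    m_out = m.copy()
    np.fill_diagonal(m_out, np.nan)
    return MISummary(
        pair_mi=m_out,
        node_means=node_means,
        network_mi=float(node_means.mean()),
    )
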