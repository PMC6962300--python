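"""Overlap (redundancy) statistics of response activation patterns.

The overlap of two ternary patterns is the fraction of nodes in exactly the
same state — including silent-silent agreements, so an over-thresholded
network whose responses are all zero has overlap 1.  Equivalently it is one
minus the normalized Hamming distance.  The batch summary averages over all
unordered pattern pairs; high values mean redundant (interfering) responses,
and the threshold sweep looks for the interior minimum where patterns are
most diverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from connectoflux.transfer import ResponseBatch

__all__ = ["OverlapSummary", "overlap_pair", "mean_overlap"]


@dataclass(frozen=True)
class OverlapSummary:
    mean_overlap: float
    pair_count: int


def overlap_pair(Ra: npt.NDArray, Rb: npt.NDArray) -> float:
    """Fraction of positions where the two patterns agree exactly."""
    a = np.asarray(Ra)
    b = np.asarray(Rb)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("patterns must be 1-D and of equal length")
    return float(np.mean(a == b))


def mean_overlap(R_batch: ResponseBatch) -> OverlapSummary:
    """Average overlap over all unordered pairs of the K response patterns.

    Computed via per-state indicator Gram matrices, so the K(K-1)/2 pairwise
    comparisons cost three K x N x K products instead of a Python loop.
    """
    K, N = R_batch.states.shape
    if K < 2:
        raise ValueError("need at least two patterns to compare")
    matches = np.zeros((K, K))
    for s in (-1, 0, 1):
        ind = (R_batch.states == s).astype(float)
        matches += ind @ ind.T
    iu = np.triu_indices(K, k=1)
    return OverlapSummary(
        mean_overlap=float(matches[iu].mean() / N),
        pair_count=K * (K - 1) // 2,
    )
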