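"""Connectivity-matrix containers, text I/O, thresholding and subsampling.

A connectome is stored as a symmetric N x N weight matrix ``w_ij`` (Pearson
correlations for functional data, tract strengths for structural data).
Networks under study are obtained by discarding weak connections: the
subject-specific cut-off is

    w_t = <|w|> + n * sigma_|w|

computed over the off-diagonal entries, with the multiplier ``n`` the swept
parameter.  Connections survive only when ``|w_ij| > w_t`` (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt

__all__ = [
    "ConnectivityMatrix",
    "ThresholdSpec",
    "ThresholdedNetwork",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "compute_threshold",
    "apply_threshold",
    "subsample_nodes",
]

_SYMMETRY_ATOL = 1e-6

_DELIMITERS = {"whitespace": None, "comma": ",", "tab": "\t"}


class MatrixFormatError(ValueError):
    """Raised when a connectivity-matrix file is malformed."""


@dataclass
class ConnectivityMatrix:
    """A subject-level symmetric weight matrix with zeroed diagonal.

    Parameters
    ----------
    subject_id
        Identifier, typically the file stem the matrix was read from.
    weights
        N x N float array, symmetric to 1e-9, zero diagonal.
    node_labels
        Optional region names, one per node.
    """

    subject_id: str
    weights: npt.NDArray[np.float64]
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise MatrixFormatError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise MatrixFormatError("connectivity matrix needs at least 2 nodes")
        if not np.allclose(w, w.T, atol=1e-9):
            raise MatrixFormatError("weights not symmetric to 1e-9")
        if np.any(np.diag(w) != 0.0):
            raise MatrixFormatError("diagonal must be zero after ingestion")
        if self.node_labels is not None and len(self.node_labels) != w.shape[0]:
            raise MatrixFormatError("node_labels length does not match matrix size")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdSpec:
    """Cut-off w_t = mean_abs_w + n * sd_abs_w for one matrix."""

    n: float
    mean_abs_w: float
    sd_abs_w: float

    @property
    def w_t(self) -> float:
        return self.mean_abs_w + self.n * self.sd_abs_w


@dataclass
class ThresholdedNetwork:
    """Weights surviving |w_ij| > w_t, plus the binary adjacency.

    ``response_threshold`` is the effective band half-width t* = max(w_t, 0)
    used to classify pre-activations into ternary states; a negative cut-off
    retains every connection and classification reduces to the plain sign.
    """

    spec: ThresholdSpec
    weights: npt.NDArray[np.float64]
    adjacency: npt.NDArray[np.int8] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def response_threshold(self) -> float:
        return max(self.spec.w_t, 0.0)


def read_matrix(
    path: str | Path,
    delimiter_dialect: str = "whitespace",
    node_labels_path: str | Path | None = None,
) -> ConnectivityMatrix:
    """Read a plain-text N x N matrix file into a :class:`ConnectivityMatrix`.

    The diagonal is zeroed (self-correlations are artifacts) and near-symmetric
    input is symmetrized as (w_ij + w_ji)/2; asymmetry beyond 1e-6 triggers a
    warning, not an error.  The subject id is the file stem.
    """
    path = Path(path)
    if delimiter_dialect not in _DELIMITERS:
        raise ValueError(f"unknown delimiter dialect {delimiter_dialect!r}")
    sep = _DELIMITERS[delimiter_dialect]

    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.split(sep) if sep else line.split()
            row = []
            for colno, cell in enumerate(cells, start=1):
                cell = cell.strip()
                try:
                    row.append(float(cell))
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, "
                        f"column {colno}"
                    ) from None
            rows.append(row)

    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise MatrixFormatError(f"{path}: ragged rows (inconsistent column count)")
    w = np.array(rows, dtype=float)
    if w.shape[0] != w.shape[1]:
        raise MatrixFormatError(
            f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, expected square"
        )
    if w.shape[0] < 2:
        raise MatrixFormatError(f"{path}: matrix must be at least 2x2")

    max_asym = float(np.max(np.abs(w - w.T)))
    if max_asym > _SYMMETRY_ATOL:
        warnings.warn(
            f"{path}: asymmetry up to {max_asym:.3g} symmetrized by averaging",
            stacklevel=2,
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)

    labels = None
    if node_labels_path is not None:
        labels = [
            ln.strip() for ln in Path(node_labels_path).read_text().splitlines()
            if ln.strip()
        ]
    return ConnectivityMatrix(subject_id=path.stem, weights=w, node_labels=labels)


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write weights whitespace-delimited with 9 significant digits."""
    np.savetxt(path, matrix.weights, fmt="%.9g")


def _offdiag(w: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    n = w.shape[0]
    return w[~np.eye(n, dtype=bool)]


def compute_threshold(matrix: ConnectivityMatrix, n: float) -> ThresholdSpec:
    """Subject-specific cut-off from the off-diagonal |w| statistics.

    The standard deviation is the sample one (N*(N-1) - 1 denominator over
    all ordered off-diagonal entries); the distinction from the population
    form is negligible at connectome sizes but fixed here for
    reproducibility.
    """
    if matrix.n_nodes < 2:
        raise ValueError("threshold undefined for a degenerate (<2 node) matrix")
    abs_w = np.abs(_offdiag(matrix.weights))
    mean = float(np.mean(abs_w))
    sd = float(np.std(abs_w, ddof=1)) if abs_w.size > 1 else 0.0
    return ThresholdSpec(n=float(n), mean_abs_w=mean, sd_abs_w=sd)


def apply_threshold(
    matrix: ConnectivityMatrix, spec: ThresholdSpec
) -> ThresholdedNetwork:
    """Zero weights with |w_ij| <= w_t; retained weights keep their sign.

    Ties at exactly w_t are dropped (strict inequality).
    """
    w = matrix.weights
    keep = np.abs(w) > spec.w_t
    np.fill_diagonal(keep, False)
    thresholded = np.where(keep, w, 0.0)
    return ThresholdedNetwork(
        spec=spec,
        weights=thresholded,
        adjacency=keep.astype(np.int8),
    )


def subsample_nodes(
    matrix: ConnectivityMatrix, k: int, seed: int
) -> ConnectivityMatrix:
    """Principal k x k submatrix on a uniformly sampled node subset.

    Used for the robustness check that the sweep statistics do not hinge on
    the parcellation size.  Deterministic for a fixed seed; sampled indices
    are kept in ascending order so the result is reproducible and symmetric.
    """
    n = matrix.n_nodes
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    labels = (
        [matrix.node_labels[i] for i in idx] if matrix.node_labels is not None
        else None
    )
    return ConnectivityMatrix(
        subject_id=f"{matrix.subject_id}_sub{k}",
        weights=matrix.weights[np.ix_(idx, idx)].copy(),
        node_labels=labels,
    )
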