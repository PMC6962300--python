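"""Threshold/probability sweeps over matrix collections and their summaries.

The sweep evaluates every (subject, threshold multiplier n, activation
probability p) condition: threshold the matrix, push K random stimuli
through the one-step transfer model, and record mutual information,
energies, pattern overlap, largest-component fraction, clustering, and the
strength-distribution fit as one row.  Aggregation averages each metric per
condition across subjects (per-subject metrics first, subject statistics
second), and ``correlate`` produces the threshold-indexed scatter of two
aggregated quantities with its Pearson coefficient and peak locations.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from connectoflux.energy import energy_report
from connectoflux.info import network_mi
from connectoflux.matrices import (
    ConnectivityMatrix,
    apply_threshold,
    compute_threshold,
    read_matrix,
)
from connectoflux.patterns import mean_overlap
from connectoflux.structure import (
    clustering_coefficient,
    fit_strength_model,
    largest_component_fraction,
    node_strengths,
)
from connectoflux.transfer import sample_stimuli, simulate

__all__ = [
    "SweepConfig",
    "METRIC_COLUMNS",
    "load_matrix_dir",
    "run_sweep",
    "aggregate",
    "correlate",
    "CorrelationResult",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "mi",
    "E_W",
    "E_H",
    "E_A",
    "EH_over_EW",
    "EW_over_EA",
    "overlap",
    "lcc_fraction",
    "C",
    "ks_D",
    "gamma",
]


def _default_n_grid() -> list[float]:
    return [round(-2.0 + 0.2 * i, 10) for i in range(21)]


@dataclass
class SweepConfig:
    """Sweep conditions: ascending threshold grid, activation probabilities,
    stimuli per condition, and the root seed all stimulus streams derive
    from."""

    n_grid: Sequence[float] = field(default_factory=_default_n_grid)
    p_values: Sequence[float] = (0.1, 0.05, 0.01)
    K: int = 100
    root_seed: int = 0
    subject_limit: int | None = None
    fit_strengths: bool = True

    def __post_init__(self) -> None:
        grid = [float(v) for v in self.n_grid]
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("n_grid must be non-empty and strictly ascending")
        if any(not 0.0 <= p <= 0.5 for p in self.p_values):
            raise ValueError("all p must lie in [0, 0.5]")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        self.n_grid = grid
        self.p_values = [float(p) for p in self.p_values]


def load_matrix_dir(
    path: str | Path, delimiter_dialect: str = "whitespace"
) -> list[ConnectivityMatrix]:
    """Read every matrix file in a directory, sorted by name."""
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no matrix files found in {path}")
    return [read_matrix(f, delimiter_dialect) for f in files]


def run_sweep(
    matrices: Iterable[ConnectivityMatrix] | str | Path,
    config: SweepConfig | None = None,
) -> pd.DataFrame:
    """Evaluate all metrics for every (subject, n, p) condition.

    Stimulus randomness is keyed deterministically by (root_seed, subject
    index, n index, p index), so identical configurations give bit-identical
    tables.  Per-subject failures are logged and skipped rather than
    aborting the sweep.
    """
    config = config or SweepConfig()
    if isinstance(matrices, (str, Path)):
        matrices = load_matrix_dir(matrices)

    rows: list[dict] = []
    n_subjects = 0
    for s_idx, matrix in enumerate(matrices):
        if config.subject_limit is not None and s_idx >= config.subject_limit:
            break
        t0 = time.perf_counter()
        try:
            rows.extend(_sweep_one_subject(matrix, s_idx, config))
        except Exception:
            logger.exception("subject %s failed; skipping", matrix.subject_id)
            continue
        n_subjects += 1
        logger.info(
            "subject %s done in %.2fs", matrix.subject_id, time.perf_counter() - t0
        )
    if not rows:
        raise ValueError("no matrices were processed")
    logger.info("sweep complete: %d subjects, %d rows", n_subjects, len(rows))
    return pd.DataFrame(rows)


def _sweep_one_subject(
    matrix: ConnectivityMatrix, s_idx: int, config: SweepConfig
) -> list[dict]:
    rows = []
    for n_idx, n in enumerate(config.n_grid):
        spec = compute_threshold(matrix, n)
        net = apply_threshold(matrix, spec)
        e_w = int(net.adjacency.sum())
        lcc = largest_component_fraction(net)
        c = clustering_coefficient(net)
        gamma = ks_d = math.nan
        if config.fit_strengths:
            try:
                fit = fit_strength_model(node_strengths(net))
                gamma, ks_d = fit.gamma, fit.ks_D
            except ValueError:
                pass  # degenerate strengths at extreme thresholds
        for p_idx, p in enumerate(config.p_values):
            rng = np.random.default_rng(
                [config.root_seed, s_idx, n_idx, p_idx]
            )
            stimuli = sample_stimuli(matrix.n_nodes, p, config.K, rng)
            responses = simulate(net, stimuli)
            mi = network_mi(stimuli, responses)
            energies = energy_report(net, responses)
            overlap = mean_overlap(responses)
            rows.append(
                {
                    "subject_id": matrix.subject_id,
                    "n": n,
                    "p": p,
                    "mi": mi.network_mi,
                    "E_W": e_w,
                    "E_H": energies.E_H,
                    "E_A": energies.E_A,
                    "EH_over_EW": energies.eh_over_ew,
                    "EW_over_EA": energies.ew_over_ea,
                    "overlap": overlap.mean_overlap,
                    "lcc_fraction": lcc,
                    "C": c,
                    "ks_D": ks_d,
                    "gamma": gamma,
                }
            )
    return rows


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean and sample sd of every metric per (n, p) condition.

    With a single subject the sd columns are NaN (undefined), matching the
    flagged-not-thrown convention used elsewhere.
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty sweep table")
    grouped = table.groupby(["n", "p"], sort=True)[METRIC_COLUMNS]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    out = means.join(sds, lsuffix="_mean", rsuffix="_sd").reset_index()
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """Threshold-indexed (x, y) series with its Pearson coefficient.

    ``r`` is NaN (flagged undefined) when either column has zero variance.
    ``x_argmax_n`` etc. locate each quantity's extremum on the threshold
    grid — the peak-localization readout of the sweep.
    """

    x: str
    y: str
    series: pd.DataFrame
    r: float
    x_argmax_n: float
    x_argmin_n: float
    y_argmax_n: float
    y_argmin_n: float


def correlate(aggregated: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Correlate two aggregated metric columns across threshold conditions.

    Expects a table for a single p (e.g. one slice of :func:`aggregate`)
    with an ``n`` column; rows where either value is NaN are dropped.
    """
    for col in ("n", x, y):
        if col not in aggregated.columns:
            raise KeyError(f"column {col!r} not in aggregated table")
    sub = aggregated[["n", x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 conditions to correlate")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(xv, yv).statistic)
    nv = sub["n"].to_numpy(dtype=float)
    return CorrelationResult(
        x=x,
        y=y,
        series=sub.reset_index(drop=True),
        r=r,
        x_argmax_n=float(nv[np.argmax(xv)]),
        x_argmin_n=float(nv[np.argmin(xv)]),
        y_argmax_n=float(nv[np.argmax(yv)]),
        y_argmin_n=float(nv[np.argmin(yv)]),
    )
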