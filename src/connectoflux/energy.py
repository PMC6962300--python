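"""Network energies of activation states.

Three complementary costs of a thresholded network and a ternary activation
state R:

* wiring cost  E_W = sum_{i,j} a_ij      (ordered pairs; structural budget)
* Hopfield energy  E_H = -sum_{i,j} r_i w~_ij r_j   (signed, bias-free)
* activity cost  E_A = sum_{i,j} |r_i w~_ij r_j|    (unsigned interaction load)

All sums run over ordered off-diagonal pairs, so each undirected edge is
counted twice; no factor 1/2 is applied anywhere, which keeps the
normalized ratios E_H/E_W and E_W/E_A internally consistent.  Bias terms of
the classical Hopfield energy are dropped (nodes are treated as
homogeneous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from connectoflux.matrices import ThresholdedNetwork
from connectoflux.transfer import ResponseBatch

__all__ = [
    "EnergyReport",
    "wiring_cost",
    "hopfield_energy",
    "activity_cost",
    "energy_report",
]


@dataclass
class EnergyReport:
    """Batch-averaged energies and the normalized ratios.

    ``eh_over_ew`` and ``ew_over_ea`` are NaN when the denominator is zero
    (empty network / all-silent responses); the paired flags record that the
    ratio is undefined rather than raising.
    """

    E_W: int
    E_H: float
    E_A: float
    eh_over_ew: float
    ew_over_ea: float

    @property
    def eh_over_ew_defined(self) -> bool:
        return not math.isnan(self.eh_over_ew)

    @property
    def ew_over_ea_defined(self) -> bool:
        return not math.isnan(self.ew_over_ea)


def wiring_cost(net: ThresholdedNetwork) -> int:
    """Number of retained connections over ordered pairs (even by symmetry)."""
    return int(net.adjacency.sum())


def hopfield_energy(net: ThresholdedNetwork, R: npt.NDArray) -> float:
    """Bias-free Hopfield energy -sum_{i != j} r_i w~_ij r_j of one state."""
    r = np.asarray(R, dtype=float)
    if r.shape != (net.n_nodes,):
        raise ValueError("state length does not match network size")
    return float(-(r @ net.weights @ r))


def activity_cost(net: ThresholdedNetwork, R: npt.NDArray) -> float:
    """Unsigned interaction load sum_{i != j} |r_i w~_ij r_j| of one state."""
    r = np.abs(np.asarray(R, dtype=float))
    if r.shape != (net.n_nodes,):
        raise ValueError("state length does not match network size")
    return float(r @ np.abs(net.weights) @ r)


def energy_report(net: ThresholdedNetwork, R_batch: ResponseBatch) -> EnergyReport:
    """Batch means of E_H and E_A with the ratios E_H/E_W and E_W/E_A."""
    if R_batch.K < 1:
        raise ValueError("need at least one response state")
    states = R_batch.states.astype(float)  # K x N
    e_h = float(-((states @ net.weights) * states).sum(axis=1).mean())
    a = np.abs(states)
    e_a = float(((a @ np.abs(net.weights)) * a).sum(axis=1).mean())
    e_w = wiring_cost(net)
    return EnergyReport(
        E_W=e_w,
        E_H=e_h,
        E_A=e_a,
        eh_over_ew=e_h / e_w if e_w > 0 else math.nan,
        ew_over_ea=e_w / e_a if e_a > 0 else math.nan,
    )
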