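"""One-step ternary information transfer on a thresholded network.

Stimuli are random ternary vectors S in {-1, 0, +1}^N: each node is +1 with
probability p, -1 with probability p, and silent otherwise.  The response of
node j is the thresholded weighted input

    r_j = sigma( sum_{i != j} w~_ij s_i ),

where w~ are the thresholded weights and sigma classifies the pre-activation
r^_j against the band [-t*, t*] with t* = max(w_t, 0): +1 above the band, -1
below, 0 inside (a negative cut-off degenerates to the plain sign rule, with
0 mapping to 0).  The model is single-step: responses are not fed back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from connectoflux.matrices import ThresholdedNetwork

__all__ = ["StimulusBatch", "ResponseBatch", "sample_stimuli", "respond", "simulate"]


@dataclass
class StimulusBatch:
    """K ternary stimulus vectors drawn with activation probability p."""

    states: npt.NDArray[np.int8]  # K x N
    p: float
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


@dataclass
class ResponseBatch:
    """Responses to a stimulus batch, with raw pre-activations retained."""

    states: npt.NDArray[np.int8]  # K x N
    pre_activation: npt.NDArray[np.float64] = field(repr=False)  # K x N
    network: ThresholdedNetwork | None = None

    @property
    def K(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


def sample_stimuli(
    N: int, p: float, K: int, seed: int | np.random.Generator
) -> StimulusBatch:
    """Sample K i.i.d. ternary stimuli: P(+1) = P(-1) = p, P(0) = 1 - 2p."""
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"activation probability must lie in [0, 0.5], got {p}")
    if N < 1 or K < 1:
        raise ValueError("N and K must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = rng.uniform(size=(K, N))
    states = np.zeros((K, N), dtype=np.int8)
    states[u < p] = 1
    states[(u >= p) & (u < 2 * p)] = -1
    return StimulusBatch(
        states=states,
        p=p,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def _classify(pre: npt.NDArray[np.float64], t_star: float) -> npt.NDArray[np.int8]:
    out = np.zeros(pre.shape, dtype=np.int8)
    out[pre > t_star] = 1
    out[pre < -t_star] = -1
    return out


def respond(
    net: ThresholdedNetwork, stimulus: npt.NDArray
) -> tuple[npt.NDArray[np.int8], npt.NDArray[np.float64]]:
    """Single-stimulus transfer: returns (ternary response, pre-activation)."""
    s = np.asarray(stimulus)
    if s.shape != (net.n_nodes,):
        raise ValueError(
            f"stimulus length {s.shape} does not match network size {net.n_nodes}"
        )
    pre = net.weights @ s.astype(float)
    return _classify(pre, net.response_threshold), pre


def simulate(net: ThresholdedNetwork, batch: StimulusBatch) -> ResponseBatch:
    """Apply :func:`respond` to each stimulus in the batch, preserving order."""
    if batch.n_nodes != net.n_nodes:
        raise ValueError("stimulus batch and network sizes differ")
    pre = batch.states.astype(float) @ net.weights  # symmetric: W s per row
    return ResponseBatch(
        states=_classify(pre, net.response_threshold),
        pre_activation=pre,
        network=net,
    )
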