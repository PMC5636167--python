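"""Plasticity and homeostasis rules.

Four interacting mechanisms keep the two plastic layers learning yet stable:

* **STDP traces** - each pre/post spike pairing within the coincidence window
  produces a signed tag ``tr = +/- K * exp(-|dt|/T_c)`` (pre-before-post
  positive).  Input->hidden tags are applied immediately (non-rewarded STDP);
  hidden->output tags are stored for six epochs and converted into weight
  changes only when a reward/punishment signal arrives.
* **Reward-gated update** - stored tags multiply the weight by
  ``1 + (Wi0/Wi) * Delta_k`` with ``Delta_k = s_rp * tr_k/(t-t_k+c) *
  Sum_tr/Avg_tr``: the ``Wi0/Wi`` term damps growth for presynaptic cells
  whose total output already exceeds its initial value (output balancing) and
  the ``Sum_tr/Avg_tr`` term divides by the synapse's running average tag
  (trace normalization), handicapping chronically active synapses.
* **Homeostatic scaling** - each cell's target input sum drifts by a factor
  (1 +/- D_tar) per epoch to push its long-run firing rate toward a set point.
* **Heterosynaptic rescaling** - after any weight change, all of a cell's
  incoming excitatory weights are multiplied by ``S_f = W_j0 / sum_i W_ij`` so
  the input sum equals the target exactly, forcing synapses to compete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import apply_reward_kernel
from .neuron import DT_MS

__all__ = [
    "StdpParams",
    "Trace",
    "RewardSignal",
    "TraceStore",
    "TraceNormalizer",
    "stdp_trace_value",
    "collect_pairings",
    "apply_unrewarded_stdp",
    "sum_traces",
    "apply_reward",
    "homeostatic_update",
    "heterosynaptic_rescale",
]


@dataclass(frozen=True)
class StdpParams:
    """Constants of the trace algebra and its normalizers.

    K : peak tag magnitude (0.04); sign set by pairing order.
    t_c_ms : exponential time constant of the pairing window, 40 ms.
    pairing_window_ms : maximum |dt| that still produces a tag.  3 * T_c by
        default, beyond which the tag has decayed below 5% of K.
    trace_lifetime : storage lifetime of a hidden->output tag, in epochs.
    c_epochs : recency-softening constant in the 1/(t - t_k + c) factor.
    delta : EMA rate of the per-synapse average tag sum.
    d_tar : homeostatic step size per epoch.
    """

    k: float = 0.04
    t_c_ms: float = 40.0
    pairing_window_ms: float = 120.0
    trace_lifetime: int = 6
    c_epochs: float = 1.0
    delta: float = 0.001
    d_tar: float = 1e-4

    def __post_init__(self) -> None:
        if self.k <= 0 or self.t_c_ms <= 0:
            raise ValueError("K and T_c must be positive")
        if self.trace_lifetime < 1:
            raise ValueError("trace_lifetime must be >= 1")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")


@dataclass(frozen=True)
class Trace:
    """A stored STDP tag on one synapse."""

    pre_index: int
    post_index: int
    value: float
    t_k: int  # creation epoch


@dataclass(frozen=True)
class RewardSignal:
    """Global reward/punishment scaling factor for one epoch.

    +1 for food, -0.5 for toxic food, -0.1 (simple task) or -0.01 (pattern
    task) when no food was obtained.
    """

    s_rp: float


def stdp_trace_value(t_pre_ms: float, t_post_ms: float, params: StdpParams) -> float:
    """Signed tag value for one spike pairing, or 0 outside the window.

    Positive ``+K exp(-|dt|/T_c)`` when the postsynaptic spike does not
    precede the presynaptic one (zero lag counts as pre-before-post),
    negative otherwise.
    """
    dt = abs(t_post_ms - t_pre_ms)
    if dt > params.pairing_window_ms:
        return 0.0
    mag = params.k * np.exp(-dt / params.t_c_ms)
    return float(mag if t_post_ms >= t_pre_ms else -mag)


def collect_pairings(pre_spikes_ms, post_spikes_ms, params: StdpParams,
                     pre_index: int = 0, post_index: int = 0, epoch: int = 0):
    """All-to-all pairing of two spike trains within the coincidence window.

    Every (pre spike, post spike) pair whose lag is inside the window yields
    one :class:`Trace`; spike lists are in milliseconds.
    """
    traces = []
    for tp in pre_spikes_ms:
        for tq in post_spikes_ms:
            val = stdp_trace_value(tp, tq, params)
            if val != 0.0:
                traces.append(Trace(pre_index, post_index, val, epoch))
    return traces


def apply_unrewarded_stdp(weights_in, traces, w_target, w_max, learning_rate: float = 1.0):
    """Immediate application of tags to one cell's incoming weight vector.

    Each tag is added (scaled by ``learning_rate``) to its synapse, clipped to
    [0, w_max], and the whole vector is then heterosynaptically rescaled so
    the input sum returns to ``w_target``.  Returns the new vector.
    """
    w = np.asarray(weights_in, dtype=float).copy()
    for tr in traces:
        w[tr.pre_index] = np.clip(w[tr.pre_index] + learning_rate * tr.value, 0.0, w_max)
    if traces:
        w = heterosynaptic_rescale(w, w_target)
    return w


def sum_traces(traces, t_now: int, c: float = 1.0) -> float:
    """Recency-weighted tag sum  sum_k tr_k / (t - t_k + c), epoch units."""
    return float(sum(tr.value / (t_now - tr.t_k + c) for tr in traces))


@dataclass
class TraceNormalizer:
    """Per-synapse running average of the recency-weighted tag sum.

    ``avg_tr`` is an EMA updated every epoch; until a synapse produces its
    first nonzero sum the normalization ratio is clamped to 1 (burn-in).
    """

    avg_tr: np.ndarray
    initialized: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "TraceNormalizer":
        return cls(np.zeros(shape), np.zeros(shape, dtype=np.bool_))


@dataclass
class TraceStore:
    """Hidden->output tags with a fixed lifetime in epochs.

    Stored per creation epoch so pruning is O(1); ``live_arrays`` concatenates
    the unexpired tags into flat arrays for the reward kernel.
    """

    lifetime: int = 6
    _by_epoch: dict = field(default_factory=dict)

    def add_arrays(self, epoch: int, pre, post, val) -> None:
        if len(pre):
            self._by_epoch.setdefault(epoch, []).append(
                (np.asarray(pre, dtype=np.int64),
                 np.asarray(post, dtype=np.int64),
                 np.asarray(val, dtype=np.float64))
            )

    def add(self, trace: Trace) -> None:
        self.add_arrays(trace.t_k, [trace.pre_index], [trace.post_index], [trace.value])

    def prune(self, t_now: int) -> None:
        """Erase tags strictly older than ``lifetime`` epochs."""
        for e in [e for e in self._by_epoch if t_now - e > self.lifetime]:
            del self._by_epoch[e]

    def live_arrays(self, t_now: int):
        pres, posts, vals, epochs = [], [], [], []
        for e, chunks in self._by_epoch.items():
            if t_now - e > self.lifetime:
                continue
            for pre, post, val in chunks:
                pres.append(pre)
                posts.append(post)
                vals.append(val)
                epochs.append(np.full(len(pre), e, dtype=np.int64))
        if not pres:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0), z
        return (np.concatenate(pres), np.concatenate(posts),
                np.concatenate(vals), np.concatenate(epochs))

    def __len__(self) -> int:
        return sum(len(c[0]) for chunks in self._by_epoch.values() for c in chunks)


def apply_reward(
    weights_out: np.ndarray,
    store: TraceStore,
    normalizer: TraceNormalizer,
    w_i0: np.ndarray,
    signal: RewardSignal,
    t_now: int,
    params: StdpParams,
    w_max: float = np.inf,
    w_floor: float = 0.0,
    ratio_max: float = 1e3,
    normalization_on: bool = True,
    balancing_on: bool = True,
) -> None:
    """Reward-gated multiplicative update of the hidden->output matrix.

    Mutates ``weights_out`` (shape n_hidden x n_output) and the normalizer in
    place.  ``w_i0`` holds each presynaptic cell's initial total output (the
    output-balancing reference).  Multiplicative factors are floored at 0 and
    weights capped at ``w_max``; the Sum_tr/Avg_tr ratio is clamped to
    ``+/-ratio_max`` as a numerical guard.
    """
    store.prune(t_now)
    pre, post, val, epochs = store.live_arrays(t_now)
    apply_reward_kernel(
        weights_out, np.asarray(w_i0, dtype=float),
        normalizer.avg_tr, normalizer.initialized,
        pre, post, val, epochs, len(pre),
        float(t_now), params.c_epochs, signal.s_rp, params.delta,
        ratio_max, w_max, w_floor, normalization_on, balancing_on,
    )


def homeostatic_update(w_j0: float, spike_rate: float, target_rate: float,
                       d_tar: float = 1e-4) -> float:
    """One homeostatic step of a cell's target input sum.

    Multiplies by (1 + d_tar) below the target rate, (1 - d_tar) above it,
    and leaves the target unchanged at exact equality.
    """
    if spike_rate < target_rate:
        return w_j0 * (1.0 + d_tar)
    if spike_rate > target_rate:
        return w_j0 * (1.0 - d_tar)
    return w_j0


def heterosynaptic_rescale(weights_in_of_cell, w_j0: float) -> np.ndarray:
    """Multiply a cell's incoming weights by S_f = w_j0 / sum(w) exactly.

    Raises on a degenerate (all-zero) input vector.
    """
    w = np.asarray(weights_in_of_cell, dtype=float)
    s = w.sum()
    if s <= 0.0:
        raise ValueError("degenerate cell: non-positive input sum")
    return w * (w_j0 / s)


def ms_per_epoch(epoch_steps: int) -> float:
    """Epoch duration in milliseconds (epoch_steps map steps at 0.5 ms)."""
    return epoch_steps * DT_MS
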