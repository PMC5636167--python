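"""First-order kinetic synapse with multiplicative release noise.

A presynaptic spike increments the postsynaptic conductance by the synaptic
weight (scaled into conductance units and jittered by release noise); between
spikes the conductance relaxes geometrically at rate ``gamma`` per step.
Feedforward inhibition is "virtual": every cell also sends an inhibitory
connection to each of its excitatory targets, whose weight always equals the
mean of the cell's excitatory output weights, so total inhibition tracks
total excitation without modelling interneurons explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "conductance_step",
    "synaptic_current",
    "mirror_inhibition",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic-synapse parameters.

    gamma
        Conductance relaxation factor per 0.5 ms step, in [0, 1).  The default
        0.9 gives a decay constant of roughly 5 ms.
    gamma_inh, inh_delay_steps
        Inhibitory conductances may decay at their own rate and arrive a step
        after excitation (feedforward inhibition via compact interneurons is
        nearly, but not exactly, synchronous with excitation).
    release_cv
        Coefficient of variability R of synaptic release; each release is
        scaled by a factor drawn uniformly from [1-R, 1+R].
    v_rp_exc, v_rp_inh
        Dimensionless reversal potentials distinguishing excitatory from
        inhibitory synapses (about -15 mV and -70 mV after conversion).
    """

    gamma: float = 0.9
    gamma_inh: float = 0.9
    inh_delay_steps: int = 1
    release_cv: float = 0.12
    v_rp_exc: float = 0.0
    v_rp_inh: float = -1.1
    v_rp_inh_out: float | None = None  # hidden->output inhibitory reversal

    @property
    def v_rp_inh_hidden(self) -> float:
        return self.v_rp_inh

    @property
    def v_rp_inh_output(self) -> float:
        return self.v_rp_inh if self.v_rp_inh_out is None else self.v_rp_inh_out

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if self.release_cv < 0.0:
            raise ValueError("release_cv must be non-negative")


def conductance_step(
    g: float,
    g_strength: float,
    w_target_post: float,
    pre_spiked: bool,
    x: float,
    params: SynapseParams,
) -> float:
    """One step of the kinetic conductance.

    Returns ``gamma*g`` plus, if the presynaptic cell spiked, a release of
    ``(1 + x*R) * g_strength / w_target_post`` where ``x`` is the noise draw
    in [-1, 1] and ``w_target_post`` the postsynaptic normalizing sum.
    """
    if w_target_post <= 0.0:
        raise ValueError("w_target_post must be positive")
    g_new = params.gamma * g
    if pre_spiked:
        g_new += (1.0 + x * params.release_cv) * g_strength / w_target_post
    return g_new


def synaptic_current(g: float, v_post: float, v_rp: float) -> float:
    """Synaptic current -g * (v_post - v_rp).

    Depolarizing (positive) for an excitatory synapse whenever the
    postsynaptic membrane sits below the reversal potential.
    """
    return -g * (v_post - v_rp)


def mirror_inhibition(excitatory_weights_of_cell) -> float:
    """Uniform inhibitory weight mirroring a cell's excitatory outputs.

    Returns the mean of the excitatory output weights; used as the weight of
    the inhibitory connection to *every* target of that cell, so the summed
    inhibitory output equals the summed excitatory output.
    """
    w = np.asarray(excitatory_weights_of_cell, dtype=float)
    if w.size == 0:
        raise ValueError("cell has no excitatory outputs to mirror")
    return float(w.mean())
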