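"""Discrete-time map model of a fast-spiking neuron.

The membrane is a two-variable difference-equation ("map") neuron: a fast
voltage-like variable ``v`` iterated through a piecewise nonlinearity and a
slow recovery variable ``i_slow``.  With the default parameters the map has a
stable subthreshold fixed point (it is silent without input) and responds to a
brief depolarizing pulse with a single spike, mimicking a fast-spiking
interneuron.  One map step corresponds to 0.5 ms of real time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels

__all__ = [
    "NeuronParams",
    "NeuronState",
    "f_alpha",
    "rulkov_step",
    "v_to_mv",
    "mv_to_v",
    "rest_state",
    "DT_MS",
]

#: Duration of one map step in milliseconds.
DT_MS = 0.5


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the map neuron.

    alpha
        Nonlinearity parameter of the fast subsystem (> 0).
    mu
        Rate of the slow variable; must satisfy 0 < mu << 1.
    sigma
        Constant bias of the slow variable; the default 0.06 puts the resting
        point in the excitable (silent) regime.
    beta_e, sigma_e
        Coupling of external/synaptic current into the fast and slow
        equations respectively.
    """

    alpha: float = 3.65
    mu: float = 0.0005
    sigma: float = 0.06
    beta_e: float = 0.133
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError("mu must satisfy 0 < mu << 1")
        if self.alpha <= 0.0:
            raise ValueError("alpha must be positive")


@dataclass
class NeuronState:
    """Per-cell dynamical state.

    ``v_prev`` is carried because the peak branch of the nonlinearity
    conditions on the voltage two steps back.
    """

    v: float
    v_prev: float
    i_slow: float
    spiked: bool = False


def f_alpha(v: float, v_prev: float, i: float, params: NeuronParams) -> float:
    """Piecewise map nonlinearity.

    Branch 1 (subthreshold, v <= 0): alpha/(1-v) - 1 + i.
    Branch 2 (spike peak, 0 < v < alpha+i and v_prev <= 0): alpha + i.
    Branch 3 (reset): -1.
    """
    if v <= 0.0 and v == 1.0:  # pragma: no cover - unreachable guard
        raise ValueError("invalid state: v == 1 on the subthreshold branch")
    return float(_kernels.f_alpha(v, v_prev, i, params.alpha))


def rulkov_step(state: NeuronState, params: NeuronParams, i_ext: float = 0.0) -> NeuronState:
    """Advance the map by one step under external drive ``i_ext``.

    The drive enters the fast equation scaled by ``beta_e`` and the slow
    equation scaled by ``sigma_e``.  The spike flag is set exactly on the step
    where the peak branch fires.
    """
    v, v_prev, i_slow, spiked = _kernels.rulkov_update(
        state.v,
        state.v_prev,
        state.i_slow,
        i_ext,
        params.alpha,
        params.mu,
        params.sigma,
        params.beta_e,
        params.sigma_e,
    )
    return NeuronState(v=float(v), v_prev=float(v_prev), i_slow=float(i_slow), spiked=bool(spiked))


def v_to_mv(v):
    """Convert the dimensionless membrane variable to millivolts: 50*v - 15."""
    return 50.0 * np.asarray(v) - 15.0 if np.ndim(v) else 50.0 * v - 15.0


def mv_to_v(v_ph):
    """Inverse of :func:`v_to_mv`."""
    return (np.asarray(v_ph) + 15.0) / 50.0 if np.ndim(v_ph) else (v_ph + 15.0) / 50.0


def rest_state(params: NeuronParams | None = None, n_steps: int = 20_000) -> NeuronState:
    """Numerically settle the map onto its silent fixed point.

    Iterates the unforced map from (v=-1, a coarse i_slow seed) for
    ``n_steps`` and returns the final state; trials start all cells from this
    resting point.
    """
    p = params or NeuronParams()
    v, v_prev, i_slow = _kernels._settle_rest(
        p.alpha, p.mu, p.sigma, p.beta_e, p.sigma_e, n_steps
    )
    return NeuronState(v=float(v), v_prev=float(v_prev), i_slow=float(i_slow))
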