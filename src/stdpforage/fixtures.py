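"""Deterministic synthetic scenarios for unit tests.

Scripted spike trains with hand-computable STDP tags, and miniature worlds
in the plain-text grid format ('.' empty, 'o' food, 'H'/'V' pattern cells,
'@' agent).  Every expected value carries a provenance note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import World, world_from_text
from .plasticity import StdpParams

__all__ = ["ScriptedScenario", "make_trace_scenarios", "make_tiny_world"]


@dataclass(frozen=True)
class ScriptedScenario:
    """A named spike-pairing scenario with its expected tag values."""

    name: str
    pre_spikes_ms: tuple
    post_spikes_ms: tuple
    expected_traces: tuple   # signed tag values, order of (pre, post) pairing
    provenance: str


def make_trace_scenarios(params: StdpParams | None = None):
    """Hand-checkable pairing scenarios for the trace algebra.

    Covers zero lag (both orders), the 40 ms (one time constant) lag, the
    window boundary, and multi-spike all-to-all pairing.
    """
    p = params or StdpParams()
    k, tc, win = p.k, p.t_c_ms, p.pairing_window_ms
    e = float(np.exp(-1.0))
    return [
        ScriptedScenario(
            "zero_lag_pre_before_post", (10.0,), (10.0,), (k,),
            "peak tag +K at zero lag"),
        ScriptedScenario(
            "zero_lag_post_before_pre", (10.0,), (9.0,),
            (-k * float(np.exp(-1.0 / tc)),),
            "post leads pre by 1 ms: -K exp(-1/Tc)"),
        ScriptedScenario(
            "one_time_constant", (0.0,), (tc,), (k * e,),
            "lag of one time constant decays the tag by e^-1"),
        ScriptedScenario(
            "window_boundary", (0.0,), (win,),
            (k * float(np.exp(-win / tc)),),
            "a pair exactly at the window edge still tags"),
        ScriptedScenario(
            "outside_window", (0.0,), (win + 1.0,), (),
            "beyond the window no tag is created"),
        ScriptedScenario(
            "multi_pair", (0.0, 1.0), (2.0,),
            (k * float(np.exp(-2.0 / tc)), k * float(np.exp(-1.0 / tc))),
            "all-to-all pairing: both pre spikes tag the one post spike"),
    ]


def make_tiny_world(layout_text: str, task: str | None = None,
                    rng_seed: int = 0) -> World:
    """Parse a miniature world from the documented grid text format.

    Raises on malformed layouts, including pattern pairs that violate the
    non-adjacency constraint.
    """
    return world_from_text(layout_text, task=task, rng=rng_seed)
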