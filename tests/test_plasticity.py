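"""Trace algebra, reward gating, homeostasis and heterosynaptic rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdpforage import (RewardSignal, StdpParams, Trace, TraceStore, apply_reward,
                        collect_pairings, heterosynaptic_rescale, homeostatic_update,
                        stdp_trace_value, sum_traces)
from stdpforage.plasticity import TraceNormalizer, apply_unrewarded_stdp


# ---------------------------------------------------------------------------
# trace values and pairing
# ---------------------------------------------------------------------------

def test_zero_lag_pre_before_post(stdp_params):
    assert stdp_trace_value(10.0, 10.0, stdp_params) == pytest.approx(0.04)


def test_zero_lag_post_before_pre(stdp_params):
    assert stdp_trace_value(10.0, 9.0, stdp_params) == pytest.approx(
        -0.04 * np.exp(-1.0 / 40.0))


def test_one_time_constant_lag(stdp_params):
    assert stdp_trace_value(0.0, 40.0, stdp_params) == pytest.approx(
        0.04 * np.exp(-1.0), abs=1e-9)
    assert stdp_trace_value(0.0, 40.0, stdp_params) == pytest.approx(0.0147151, abs=1e-6)


def test_outside_window_no_trace(stdp_params):
    assert stdp_trace_value(0.0, stdp_params.pairing_window_ms + 1, stdp_params) == 0.0


@given(dt=st.floats(0.0, 120.0))
@settings(max_examples=60, deadline=None)
def test_trace_antisymmetric_in_order(dt):
    """Swapping pre/post order flips the sign but not the magnitude."""
    params = StdpParams()
    fwd = stdp_trace_value(0.0, dt, params)
    if dt > 0:
        assert stdp_trace_value(dt, 0.0, params) == pytest.approx(-fwd)
    assert abs(fwd) <= params.k + 1e-12


def test_collect_pairings_single_pair(stdp_params):
    traces = collect_pairings([10.0], [12.0], stdp_params)
    assert len(traces) == 1
    assert traces[0].value == pytest.approx(0.04 * np.exp(-2.0 / 40.0))


def test_collect_pairings_empty(stdp_params):
    assert collect_pairings([], [5.0], stdp_params) == []


def test_collect_pairings_all_to_all(stdp_params):
    """Every in-window (pre, post) combination produces one trace."""
    pre, post = [0.0, 1.0], [2.0]
    traces = collect_pairings(pre, post, stdp_params)
    expected = [
        stdp_trace_value(tp, tq, stdp_params) for tp in pre for tq in post
        if abs(tq - tp) <= stdp_params.pairing_window_ms
    ]
    assert sorted(t.value for t in traces) == pytest.approx(sorted(expected))
    assert len(traces) == 2


# ---------------------------------------------------------------------------
# recency-weighted sums and the trace store
# ---------------------------------------------------------------------------

def test_sum_traces_fresh():
    assert sum_traces([Trace(0, 0, 0.04, t_k=5)], t_now=5) == pytest.approx(0.04)


def test_sum_traces_aged():
    assert sum_traces([Trace(0, 0, 0.04, t_k=2)], t_now=5) == pytest.approx(0.01)


def test_sum_traces_empty():
    assert sum_traces([], t_now=0) == 0.0


def test_trace_store_expiry():
    store = TraceStore(lifetime=6)
    store.add(Trace(0, 0, 0.04, t_k=0))
    store.prune(6)
    assert len(store) == 1  # still live 6 epochs after creation
    store.prune(7)
    assert len(store) == 0  # erased on the 7th


# ---------------------------------------------------------------------------
# rewarded update (multiplicative, balanced, normalized)
# ---------------------------------------------------------------------------

def _single_trace_setup(n_hidden=3, n_output=2, w=0.5, avg=0.04):
    w_out = np.full((n_hidden, n_output), w)
    w_i0 = w_out.sum(axis=1)
    store = TraceStore()
    store.add(Trace(0, 0, 0.04, t_k=0))
    norm = TraceNormalizer.zeros((n_hidden, n_output))
    norm.avg_tr[0, 0] = avg
    norm.initialized[0, 0] = True
    return w_out, w_i0, store, norm


@pytest.mark.parametrize("s_rp,factor", [(1.0, 1.04), (-0.5, 0.98)])
def test_single_fresh_trace_factor(stdp_params, s_rp, factor):
    """With all normalizers at 1 the multiplicative factor is 1 + s_rp*tr."""
    w_out, w_i0, store, norm = _single_trace_setup()
    apply_reward(w_out, store, norm, w_i0, RewardSignal(s_rp), t_now=0,
                 params=stdp_params)
    assert w_out[0, 0] == pytest.approx(0.5 * factor)
    # untagged synapses untouched
    assert w_out[1, 1] == 0.5


def test_no_traces_is_identity(stdp_params):
    w_out = np.full((3, 2), 0.5)
    store = TraceStore()
    norm = TraceNormalizer.zeros((3, 2))
    apply_reward(w_out, store, norm, w_out.sum(axis=1), RewardSignal(1.0),
                 t_now=0, params=stdp_params)
    assert np.all(w_out == 0.5)


def test_punishment_decreases_tagged_weights(stdp_params):
    """Negative reward with positive traces strictly weakens tagged synapses."""
    w_out, w_i0, store, norm = _single_trace_setup()
    before = w_out[0, 0]
    apply_reward(w_out, store, norm, w_i0, RewardSignal(-0.5), t_now=0,
                 params=stdp_params)
    assert w_out[0, 0] < before


def test_trace_normalization_damps_busy_synapses(stdp_params):
    """A synapse with a larger running trace average gets a smaller update."""
    deltas = []
    for avg in (0.04, 0.4):
        w_out, w_i0, store, norm = _single_trace_setup(avg=avg)
        apply_reward(w_out, store, norm, w_i0, RewardSignal(1.0), t_now=0,
                     params=stdp_params)
        deltas.append(w_out[0, 0] - 0.5)
    assert deltas[1] < deltas[0]


def test_output_balancing_halves_update_at_double_output(stdp_params):
    """W_i = 2*W_i0 halves the relative weight increment exactly."""
    increments = []
    for scale in (1.0, 2.0):
        w_out, w_i0, store, norm = _single_trace_setup()
        w_out *= scale  # current output sum scaled; keep the same w_i0
        apply_reward(w_out, store, norm, w_i0 / 1.0, RewardSignal(1.0),
                     t_now=0, params=stdp_params)
        increments.append(w_out[0, 0] / (0.5 * scale) - 1.0)
    assert increments[1] == pytest.approx(increments[0] / 2.0)


def test_avg_tr_ema_update(stdp_params):
    w_out, w_i0, store, norm = _single_trace_setup(avg=0.02)
    apply_reward(w_out, store, norm, w_i0, RewardSignal(1.0), t_now=0,
                 params=stdp_params)
    d = stdp_params.delta
    assert norm.avg_tr[0, 0] == pytest.approx(0.02 * (1 - d) + d * 0.04)


def test_avg_tr_burn_in_initializes_at_first_sum(stdp_params):
    w_out, w_i0, store, norm = _single_trace_setup()
    norm.initialized[0, 0] = False
    norm.avg_tr[0, 0] = 0.0
    apply_reward(w_out, store, norm, w_i0, RewardSignal(1.0), t_now=0,
                 params=stdp_params)
    # ratio clamped to 1 during burn-in -> plain factor, then avg seeded
    assert w_out[0, 0] == pytest.approx(0.5 * 1.04)
    assert norm.initialized[0, 0]
    assert norm.avg_tr[0, 0] == pytest.approx(0.04)


# ---------------------------------------------------------------------------
# non-rewarded STDP (input layer)
# ---------------------------------------------------------------------------

def test_unrewarded_stdp_conserves_input_sum():
    w = np.array([0.5, 0.5, 0.5])
    out = apply_unrewarded_stdp(w, [Trace(0, 0, 0.04, 0)], w_target=1.5, w_max=10.0)
    assert out[0] > out[1]
    assert out.sum() == pytest.approx(1.5, abs=1e-12)


def test_unrewarded_stdp_clips_at_wmax():
    w = np.array([1.0, 1.0])
    out = apply_unrewarded_stdp(w, [Trace(0, 0, 0.04, 0)], w_target=2.0, w_max=1.0)
    # clipped before rescale; sum restored to target
    assert out.sum() == pytest.approx(2.0, abs=1e-12)


def test_unrewarded_stdp_identity_without_traces():
    w = np.array([0.3, 0.7])
    assert np.all(apply_unrewarded_stdp(w, [], 1.0, 10.0) == w)


# ---------------------------------------------------------------------------
# homeostasis
# ---------------------------------------------------------------------------

def test_homeostatic_step_directions():
    assert homeostatic_update(1.0, 0.1, 0.4) == pytest.approx(1.0001)
    assert homeostatic_update(1.0, 0.9, 0.4) == pytest.approx(0.9999)
    assert homeostatic_update(1.0, 0.4, 0.4) == 1.0


def test_heterosynaptic_rescale_examples():
    assert np.allclose(heterosynaptic_rescale([2.0, 2.0], 2.0), [1.0, 1.0])
    w = np.array([0.25, 0.75])
    assert np.all(heterosynaptic_rescale(w, 1.0) == w)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_heterosynaptic_rescale_restores_target_exactly(seed):
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.01, 5.0, size=9)
    target = rng.uniform(0.1, 50.0)
    assert heterosynaptic_rescale(w, target).sum() == pytest.approx(target, abs=1e-12)


def test_heterosynaptic_rescale_degenerate():
    with pytest.raises(ValueError):
        heterosynaptic_rescale([0.0, 0.0], 1.0)
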