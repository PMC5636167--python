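"""Numba-compiled inner loops.

Everything here is deliberately flat: scalar map updates, per-step conductance
bookkeeping and spike-pairing run inside a single jitted epoch function so that
a full training run (thousands of epochs of 600 map steps each) stays cheap.
The public modules wrap these kernels with typed, documented APIs; tests
exercise the scalar functions directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# neuron map
# ---------------------------------------------------------------------------


@njit(cache=True)
def f_alpha(v, v_prev, i, alpha):
    """Piecewise map nonlinearity. `i` already includes any external drive."""
    if v <= 0.0:
        return alpha / (1.0 - v) - 1.0 + i
    if v < alpha + i and v_prev <= 0.0:
        return alpha + i
    return -1.0


@njit(cache=True)
def rulkov_update(v, v_prev, i_slow, i_ext, alpha, mu, sigma, beta_e, sigma_e):
    """One step of the two-variable map.

    Returns (v_new, v_prev_new, i_slow_new, spiked). A spike is registered on
    the step where the peak branch of f_alpha is taken.
    """
    i_arg = i_slow + beta_e * i_ext
    spiked = (v > 0.0) and (v < alpha + i_arg) and (v_prev <= 0.0)
    v_new = f_alpha(v, v_prev, i_arg, alpha)
    i_new = i_slow - mu * (v_new + 1.0) + mu * sigma + mu * sigma_e * i_ext
    return v_new, v, i_new, spiked


@njit(cache=True)
def _settle_rest(alpha, mu, sigma, beta_e, sigma_e, n_steps):
    v = -1.0
    v_prev = -1.0
    i_slow = sigma - 1.0 - alpha / (2.0 - sigma) + 1.0  # coarse seed near rest
    for _ in range(n_steps):
        v, v_prev, i_slow, _ = rulkov_update(
            v, v_prev, i_slow, 0.0, alpha, mu, sigma, beta_e, sigma_e
        )
    return v, v_prev, i_slow


@njit(cache=True)
def settle_rest_array(alpha, mu, sigmas, beta_e, sigma_e, n_steps):
    n = sigmas.shape[0]
    v = np.empty(n)
    vp = np.empty(n)
    isl = np.empty(n)
    for c in range(n):
        v[c], vp[c], isl[c] = _settle_rest(alpha, mu, sigmas[c], beta_e, sigma_e, n_steps)
    return v, vp, isl


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------
# Layer layout: input (ni cells, driven by a 2-step stimulus pulse), hidden
# (nh cells, sparse fan-in from input), output (no cells, dense from hidden).
# Conductances are aggregated per postsynaptic cell (shared decay rate gamma
# and shared reversal potentials make this exact).


@njit(cache=True, fastmath=True)
def run_epoch_kernel(
    # neuron params (per-cell sigma arrays give intrinsic heterogeneity)
    alpha, mu, sig_i, sig_h, sig_o, beta_e, sigma_e,
    # synapse params
    gamma, gamma_inh, inh_delay, release_cv, vrp_exc, vrp_inh_h, vrp_inh_o,
    g_scale_in, g_scale_out,
    # state: membrane variables per layer
    v_i, vp_i, is_i, v_h, vp_h, is_h, v_o, vp_o, is_o,
    # conductance aggregates
    ge_h, gi_h, ge_o, gi_o,
    # wiring / weights
    in2h_idx, rev_ptr, rev_h, rev_k,
    w_in, w_out, mirror_in, mirror_out,
    div_h, div_o, wtar_h,
    # plasticity params
    stdp_on_in, record_traces, k_in, k_plus, tc_steps, window_steps, wmax_in,
    # spike-time rings (global step numbers, -1 = empty)
    ring_i, ring_h, ring_o, ring_i_pos, ring_h_pos, ring_o_pos,
    # stimulus
    stim, stim_amp, stim_steps,
    # epoch geometry
    epoch_steps, half_steps, step0, epoch_index,
    # inhibition switches
    use_inh_in, use_inh_out,
    # trace output buffers
    tr_pre, tr_post, tr_val, tr_epoch,
    # delayed inhibitory increments (arrive one step after excitation)
    gi_add_h, gi_add_o,
    # active-set bookkeeping (resting cells are snapped and skipped)
    active_i, active_h, active_o,
    vr_i, vpr_i, ir_i, vr_h, vpr_h, ir_h, vr_o, vpr_o, ir_o, rest_tol,
    # rng seed for this epoch
    seed,
):
    """Simulate one epoch; returns spike counts and the number of new traces.

    Mutates membrane state, conductances, w_in (online non-rewarded STDP),
    spike rings and trace buffers in place.
    """
    np.random.seed(seed)
    ni = v_i.shape[0]
    nh = v_h.shape[0]
    no = v_o.shape[0]
    fan_in = in2h_idx.shape[1]

    counts_i = np.zeros(ni, dtype=np.int64)
    counts_h = np.zeros(nh, dtype=np.int64)
    counts_o = np.zeros(no, dtype=np.int64)
    counts_o_half = np.zeros(no, dtype=np.int64)
    n_traces = 0
    cap = tr_pre.shape[0]

    for step in range(epoch_steps):
        t = step0 + step

        # --- input layer: external pulse only
        stim_now = step < stim_steps
        for c in range(ni):
            drive = stim_amp if (stim_now and stim[c]) else 0.0
            if drive != 0.0:
                active_i[c] = 1
            elif active_i[c] == 0:
                continue
            v_new, vp_i[c], is_i[c], spk = rulkov_update(
                v_i[c], vp_i[c], is_i[c], drive, alpha, mu, sig_i[c], beta_e, sigma_e
            )
            v_i[c] = v_new
            if drive == 0.0 and (
                abs(v_new - vr_i[c]) < rest_tol
                and abs(vp_i[c] - vr_i[c]) < rest_tol
                and abs(is_i[c] - ir_i[c]) < rest_tol
            ):
                v_i[c] = vr_i[c]
                vp_i[c] = vpr_i[c]
                is_i[c] = ir_i[c]
                active_i[c] = 0
            if spk:
                counts_i[c] += 1
                ring_i[c, ring_i_pos[c]] = t
                ring_i_pos[c] = (ring_i_pos[c] + 1) % ring_i.shape[1]
                # propagate to hidden conductances
                mi = mirror_in[c]
                for p in range(rev_ptr[c], rev_ptr[c + 1]):
                    h = rev_h[p]
                    kk = rev_k[p]
                    active_h[h] = 1
                    x = np.random.uniform(-1.0, 1.0)
                    ge_h[h] += (1.0 + x * release_cv) * g_scale_in * w_in[h, kk] / div_h[h]
                    if use_inh_in:
                        x2 = np.random.uniform(-1.0, 1.0)
                        kick = (1.0 + x2 * release_cv) * g_scale_in * mi / div_h[h]
                        if inh_delay:
                            gi_add_h[h] += kick
                        else:
                            gi_h[h] += kick
                # post-before-pre STDP on input->hidden (depression)
                if stdp_on_in:
                    for p in range(rev_ptr[c], rev_ptr[c + 1]):
                        h = rev_h[p]
                        kk = rev_k[p]
                        changed = False
                        for q in range(ring_h.shape[1]):
                            ts = ring_h[h, q]
                            if ts >= 0 and 0 < t - ts <= window_steps:
                                w_in[h, kk] -= k_in * np.exp(-(t - ts) / tc_steps)
                                changed = True
                        if changed:
                            if w_in[h, kk] < 0.0:
                                w_in[h, kk] = 0.0
                            s = 0.0
                            for kk2 in range(fan_in):
                                s += w_in[h, kk2]
                            if s > 0.0:
                                sf = wtar_h[h] / s
                                for kk2 in range(fan_in):
                                    w_in[h, kk2] *= sf

        # --- hidden layer
        for h in range(nh):
            if active_h[h] == 0:
                continue
            if gi_add_h[h] != 0.0:
                gi_h[h] += gi_add_h[h]
                gi_add_h[h] = 0.0
            vh = v_h[h]
            i_syn = -ge_h[h] * (vh - vrp_exc) - gi_h[h] * (vh - vrp_inh_h)
            v_new, vp_h[h], is_h[h], spk = rulkov_update(
                vh, vp_h[h], is_h[h], i_syn, alpha, mu, sig_h[h], beta_e, sigma_e
            )
            v_h[h] = v_new
            ge_h[h] *= gamma
            gi_h[h] *= gamma_inh
            if (
                ge_h[h] < 1e-12
                and gi_h[h] < 1e-12
                and abs(v_new - vr_h[h]) < rest_tol
                and abs(vp_h[h] - vr_h[h]) < rest_tol
                and abs(is_h[h] - ir_h[h]) < rest_tol
            ):
                v_h[h] = vr_h[h]
                vp_h[h] = vpr_h[h]
                is_h[h] = ir_h[h]
                ge_h[h] = 0.0
                gi_h[h] = 0.0
                active_h[h] = 0
            if spk:
                counts_h[h] += 1
                ring_h[h, ring_h_pos[h]] = t
                ring_h_pos[h] = (ring_h_pos[h] + 1) % ring_h.shape[1]
                # propagate to output conductances
                mh = mirror_out[h]
                for j in range(no):
                    active_o[j] = 1
                    x = np.random.uniform(-1.0, 1.0)
                    ge_o[j] += (1.0 + x * release_cv) * g_scale_out * w_out[h, j] / div_o[j]
                    if use_inh_out:
                        x2 = np.random.uniform(-1.0, 1.0)
                        kick = (1.0 + x2 * release_cv) * g_scale_out * mh / div_o[j]
                        if inh_delay:
                            gi_add_o[j] += kick
                        else:
                            gi_o[j] += kick
                # pre-before-post STDP on input->hidden (potentiation)
                if stdp_on_in:
                    changed = False
                    for kk in range(fan_in):
                        c = in2h_idx[h, kk]
                        w_old = w_in[h, kk]
                        hit = False
                        for q in range(ring_i.shape[1]):
                            ts = ring_i[c, q]
                            if ts >= 0 and 0 <= t - ts <= window_steps:
                                w_in[h, kk] += k_in * np.exp(-(t - ts) / tc_steps)
                                hit = True
                        if hit:
                            changed = True
                            if w_in[h, kk] < 0.0:
                                w_in[h, kk] = 0.0
                            cap = wmax_in if wmax_in > w_old else w_old
                            if w_in[h, kk] > cap:
                                w_in[h, kk] = cap
                    if changed:
                        s = 0.0
                        for kk2 in range(fan_in):
                            s += w_in[h, kk2]
                        if s > 0.0:
                            sf = wtar_h[h] / s
                            for kk2 in range(fan_in):
                                w_in[h, kk2] *= sf
                # post-before-pre traces on hidden->output (negative tag)
                if record_traces:
                    for j in range(no):
                        for q in range(ring_o.shape[1]):
                            ts = ring_o[j, q]
                            if ts >= 0 and 0 < t - ts <= window_steps:
                                if n_traces < cap:
                                    tr_pre[n_traces] = h
                                    tr_post[n_traces] = j
                                    tr_val[n_traces] = -k_plus * np.exp(
                                        -(t - ts) / tc_steps
                                    )
                                    tr_epoch[n_traces] = epoch_index
                                    n_traces += 1

        # --- output layer
        for j in range(no):
            if active_o[j] == 0:
                continue
            if gi_add_o[j] != 0.0:
                gi_o[j] += gi_add_o[j]
                gi_add_o[j] = 0.0
            vo = v_o[j]
            i_syn = -ge_o[j] * (vo - vrp_exc) - gi_o[j] * (vo - vrp_inh_o)
            v_new, vp_o[j], is_o[j], spk = rulkov_update(
                vo, vp_o[j], is_o[j], i_syn, alpha, mu, sig_o[j], beta_e, sigma_e
            )
            v_o[j] = v_new
            ge_o[j] *= gamma
            gi_o[j] *= gamma_inh
            if (
                ge_o[j] < 1e-12
                and gi_o[j] < 1e-12
                and abs(v_new - vr_o[j]) < rest_tol
                and abs(vp_o[j] - vr_o[j]) < rest_tol
                and abs(is_o[j] - ir_o[j]) < rest_tol
            ):
                v_o[j] = vr_o[j]
                vp_o[j] = vpr_o[j]
                is_o[j] = ir_o[j]
                ge_o[j] = 0.0
                gi_o[j] = 0.0
                active_o[j] = 0
            if spk:
                counts_o[j] += 1
                if step < half_steps:
                    counts_o_half[j] += 1
                ring_o[j, ring_o_pos[j]] = t
                ring_o_pos[j] = (ring_o_pos[j] + 1) % ring_o.shape[1]
                # pre-before-post traces on hidden->output (positive tag)
                if record_traces:
                    for h in range(nh):
                        for q in range(ring_h.shape[1]):
                            ts = ring_h[h, q]
                            if ts >= 0 and 0 <= t - ts <= window_steps:
                                if n_traces < cap:
                                    tr_pre[n_traces] = h
                                    tr_post[n_traces] = j
                                    tr_val[n_traces] = k_plus * np.exp(
                                        -(t - ts) / tc_steps
                                    )
                                    tr_epoch[n_traces] = epoch_index
                                    n_traces += 1

    return counts_i, counts_h, counts_o, counts_o_half, n_traces


# ---------------------------------------------------------------------------
# rewarded STDP application (Eq 2 of the plasticity scheme)
# ---------------------------------------------------------------------------


@njit(cache=True)
def apply_reward_kernel(
    w_out, wi0, avg_tr, avg_init,
    tr_pre, tr_post, tr_val, tr_epoch, n_tr,
    t_now, c_epochs, s_rp, delta, ratio_max, wmax_out, w_floor,
    normalization_on, balancing_on,
):
    """Multiplicative reward-gated update of hidden->output weights.

    Applies W_ij <- W_ij * prod_k (1 + (Wi0/Wi) * Delta_k) over the live
    traces, with Delta_k = s_rp * tr_k/(t-t_k+c) * Sum_tr/Avg_tr, then updates
    the per-synapse trace average (EMA). Clips factors at 0 and weights at
    wmax_out. Returns nothing; mutates w_out, avg_tr, avg_init.
    """
    nh, no = w_out.shape
    # current total output per hidden cell (Eq 2's W_i), frozen for this event
    w_i = np.zeros(nh)
    for h in range(nh):
        s = 0.0
        for j in range(no):
            s += w_out[h, j]
        w_i[h] = s

    sum_tr = np.zeros((nh, no))
    for k in range(n_tr):
        sum_tr[tr_pre[k], tr_post[k]] += tr_val[k] / (t_now - tr_epoch[k] + c_epochs)

    for k in range(n_tr):
        h = tr_pre[k]
        j = tr_post[k]
        # burn-in floor: until the synapse has a positive running average,
        # the normalization ratio is clamped to 1
        if normalization_on and avg_init[h, j] and avg_tr[h, j] > 1e-12:
            ratio = sum_tr[h, j] / avg_tr[h, j]
            if ratio > ratio_max:
                ratio = ratio_max
            elif ratio < -ratio_max:
                ratio = -ratio_max
        else:
            ratio = 1.0
        d_k = s_rp * (tr_val[k] / (t_now - tr_epoch[k] + c_epochs)) * ratio
        if balancing_on and w_i[h] > 0.0:
            bal = wi0[h] / w_i[h]
        else:
            bal = 1.0
        factor = 1.0 + bal * d_k
        if factor < 0.0:
            factor = 0.0
        w_old = w_out[h, j]
        w_out[h, j] = w_old * factor
        cap = wmax_out if wmax_out > w_old else w_old
        if w_out[h, j] > cap:
            w_out[h, j] = cap
        elif w_out[h, j] < w_floor:
            # multiplicative zero is absorbing; keep a tiny regrowable floor
            w_out[h, j] = w_floor

    # trace-average EMA (burn-in: initialize at first nonzero Sum_tr)
    for h in range(nh):
        for j in range(no):
            if avg_init[h, j]:
                avg_tr[h, j] = avg_tr[h, j] * (1.0 - delta) + delta * sum_tr[h, j]
            elif sum_tr[h, j] != 0.0:
                avg_tr[h, j] = sum_tr[h, j]
                avg_init[h, j] = True


# ---------------------------------------------------------------------------
# exhaustive 5-move lookahead (heuristic baseline)
# ---------------------------------------------------------------------------

_DR = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DC = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def _clamp(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def exhaustive5_scores(field):
    """Score all 8 first moves by exhaustive 5-deep rollout within the field.

    `field` is the 7x7 boolean visual grid; the agent sits at (3,3). Rollout
    positions are clamped to the field. Score encodes (food count, earlier
    acquisition) lexicographically: each pickup at depth d (1-based)
    contributes 6**(5-d), plus 7776 per pickup so that total count dominates.
    Food eaten during a rollout is removed for the rest of that rollout.
    Returns two (8,) int64 arrays: the best achievable score per first move,
    and the number of 5-move sequences per first move attaining the global
    optimum is recoverable from them (counts are per-first-move optima).
    """
    food = field.copy()
    best = np.full(8, -1, dtype=np.int64)
    nbest = np.zeros(8, dtype=np.int64)
    side = field.shape[0]
    hi = side - 1
    ctr = side // 2

    for d1 in range(8):
        r1 = _clamp(ctr + _DR[d1], 0, hi)
        c1 = _clamp(ctr + _DC[d1], 0, hi)
        e1 = food[r1, c1]
        s1 = (7776 + 1296) if e1 else 0
        if e1:
            food[r1, c1] = False
        for d2 in range(8):
            r2 = _clamp(r1 + _DR[d2], 0, hi)
            c2 = _clamp(c1 + _DC[d2], 0, hi)
            e2 = food[r2, c2]
            s2 = s1 + ((7776 + 216) if e2 else 0)
            if e2:
                food[r2, c2] = False
            for d3 in range(8):
                r3 = _clamp(r2 + _DR[d3], 0, hi)
                c3 = _clamp(c2 + _DC[d3], 0, hi)
                e3 = food[r3, c3]
                s3 = s2 + ((7776 + 36) if e3 else 0)
                if e3:
                    food[r3, c3] = False
                for d4 in range(8):
                    r4 = _clamp(r3 + _DR[d4], 0, hi)
                    c4 = _clamp(c3 + _DC[d4], 0, hi)
                    e4 = food[r4, c4]
                    s4 = s3 + ((7776 + 6) if e4 else 0)
                    if e4:
                        food[r4, c4] = False
                    for d5 in range(8):
                        r5 = _clamp(r4 + _DR[d5], 0, hi)
                        c5 = _clamp(c4 + _DC[d5], 0, hi)
                        s5 = s4 + ((7776 + 1) if food[r5, c5] else 0)
                        if s5 > best[d1]:
                            best[d1] = s5
                            nbest[d1] = 1
                        elif s5 == best[d1]:
                            nbest[d1] += 1
                    if e4:
                        food[r4, c4] = True
                if e3:
                    food[r3, c3] = True
            if e2:
                food[r2, c2] = True
        if e1:
            food[r1, c1] = True
    return best, nbest
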