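"""Network construction, calibration, epoch dynamics and housekeeping."""

import dataclasses

import numpy as np
import pytest

from stdpforage import NetworkConfig, RewardSignal, build_network
from stdpforage.network import measure_spike_threshold


def test_default_architecture_counts():
    cfg = NetworkConfig()
    net = build_network(cfg, rng_seed=0)
    assert cfg.n_neurons == 842
    assert net.in2h_idx.shape == (784, 9)         # 7056 input->hidden synapses
    assert net.w_out.shape == (784, 9)            # 7056 hidden->output synapses
    # each hidden cell sees fan_in *distinct* inputs
    assert all(len(set(row)) == 9 for row in net.in2h_idx)


def test_initial_weights_positive_and_targets_match():
    net = build_network(NetworkConfig(), rng_seed=1)
    assert (net.w_in > 0).all()
    assert np.allclose(net.w_in.sum(axis=1), net.wtar_h)
    assert np.allclose(net.w_out, net.config.w_out_init)  # uniform initial output weights


def test_build_is_deterministic_by_seed():
    a = build_network(NetworkConfig(), rng_seed=7)
    b = build_network(NetworkConfig(), rng_seed=7)
    assert np.array_equal(a.in2h_idx, b.in2h_idx)
    assert np.array_equal(a.w_in, b.w_in)


def test_full_fan_in_limit():
    cfg = NetworkConfig(hidden_side=3, fan_in=49)
    net = build_network(cfg, rng_seed=0)
    assert all(sorted(row) == list(range(49)) for row in net.in2h_idx)


def test_fan_in_too_large_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(fan_in=50)


def test_spike_threshold_monotone_in_inhibition(neuron_params, synapse_params):
    """Mirrored inhibition raises the conductance needed to reach threshold."""
    g0 = measure_spike_threshold(neuron_params, synapse_params, inh_ratio=0.0)
    g1 = measure_spike_threshold(neuron_params, synapse_params, inh_ratio=0.5)
    assert 0 < g0 < g1


def test_zero_stimulus_silent_network():
    net = build_network(NetworkConfig(), rng_seed=2)
    rec = net.run_epoch(np.zeros(49, dtype=bool))
    assert rec.counts_input.sum() == 0
    assert rec.counts_hidden.sum() == 0
    assert rec.counts_output.sum() == 0


def test_stimulated_input_cells_spike_exactly_once():
    net = build_network(NetworkConfig(), rng_seed=3)
    stim = np.zeros(49, dtype=bool)
    stim[[5, 17, 40]] = True
    rec = net.run_epoch(stim)
    assert np.array_equal(np.flatnonzero(rec.counts_input), [5, 17, 40])
    assert np.all(rec.counts_input[stim] == 1)


def test_epoch_reproducible_with_fixed_seed():
    """Identical state and per-epoch seed give bit-identical dynamics."""
    cfg = NetworkConfig(synapse=dataclasses.replace(NetworkConfig().synapse,
                                                    release_cv=0.0),
                        input_stdp=False, reward_stdp=False)
    stim = np.zeros(49, dtype=bool)
    stim[[1, 9, 30]] = True
    outs = []
    for _ in range(2):
        net = build_network(cfg, rng_seed=11)
        rec = net.run_epoch(stim, seed=42)
        outs.append((rec.counts_hidden.copy(), net.v_h.copy(), net.is_h.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
    assert np.array_equal(outs[0][2], outs[1][2])


def test_input_sums_conserved_through_training_epoch():
    """After housekeeping every hidden cell's input sum equals its target."""
    net = build_network(NetworkConfig(), rng_seed=4)
    rng = np.random.default_rng(0)
    for _ in range(10):
        stim = rng.random(49) < 0.2
        rec = net.run_epoch(stim)
        net.apply_reward_epoch(RewardSignal(-0.1))
        net.epoch_housekeeping(rec)
    assert np.allclose(net.w_in.sum(axis=1), net.wtar_h, rtol=1e-10)
    assert np.allclose(net.w_out.sum(axis=0), net.wtar_o, rtol=1e-10)


def test_silent_cells_targets_grow_geometrically():
    """A silent output cell's target input sum grows at (1 + D_tar) per epoch."""
    net = build_network(NetworkConfig(), rng_seed=5)
    w0 = net.wtar_o.copy()
    stim = np.zeros(49, dtype=bool)
    for _ in range(50):
        rec = net.run_epoch(stim)
        net.epoch_housekeeping(rec)
    assert np.allclose(net.wtar_o, w0 * 1.0001 ** 50)


def test_trace_lifetime_enforced_by_housekeeping():
    net = build_network(NetworkConfig(), rng_seed=6)
    net.store.add_arrays(0, [1], [2], [0.04])
    net.epoch = 7
    net.store.prune(net.epoch)
    assert len(net.store) == 0


def test_mirrors_track_excitatory_means():
    net = build_network(NetworkConfig(), rng_seed=8)
    rng = np.random.default_rng(1)
    for _ in range(5):
        stim = rng.random(49) < 0.2
        rec = net.run_epoch(stim)
        net.apply_reward_epoch(RewardSignal(1.0))
        net.epoch_housekeeping(rec)
    assert np.allclose(net.mirror_out, net.w_out.mean(axis=1))
    # per input cell: mean over its outgoing excitatory weights
    sums = np.zeros(49)
    np.add.at(sums, net.in2h_idx.reshape(-1), net.w_in.reshape(-1))
    counts = np.bincount(net.in2h_idx.reshape(-1), minlength=49)
    assert np.allclose(net.mirror_in[counts > 0], (sums / counts)[counts > 0])


def test_output_inhibition_ablation_inflates_variance():
    """Removing hidden->output inhibition increases per-epoch output variance."""
    rng = np.random.default_rng(2)
    stims = rng.random((150, 49)) < 0.12
    totals = {}
    for flag in (True, False):
        net = build_network(NetworkConfig(use_inh_out=flag), rng_seed=9)
        tot = [net.run_epoch(stims[i]).counts_output.sum() for i in range(len(stims))]
        totals[flag] = np.var(tot)
    assert totals[False] > totals[True]
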