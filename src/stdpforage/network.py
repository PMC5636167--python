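"""Three-layer feedforward spiking network with mirrored inhibition.

Architecture (defaults): a 7x7 input layer driven by the visual field, a
28x28 hidden layer with sparse random fan-in (9 inputs per cell,
non-rewarded STDP), and a 3x3 output layer receiving dense connections under
rewarded STDP.  Every projecting cell also sends virtual feedforward
inhibition whose per-connection weight mirrors the mean of its excitatory
output weights.

Conductance units are calibrated at build time: the scale of each projection
is set so that a single presynaptic spike through a synapse of
``thr_mult * mean initial weight`` just reaches the postsynaptic spike
threshold (measured on the actual map neuron, noise off).  The hard weight
cap is then ``wmax_frac`` of that single-input threshold weight, so no single
input synapse can fire a cell on its own at baseline excitability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .neuron import DT_MS, NeuronParams, rest_state
from .plasticity import (RewardSignal, StdpParams, TraceNormalizer, TraceStore,
                         apply_reward)
from .synapse import SynapseParams

logger = logging.getLogger(__name__)

__all__ = ["NetworkConfig", "EpochRecord", "Network", "build_network",
           "measure_spike_threshold", "calibrate_excitability"]


@dataclass(frozen=True)
class NetworkConfig:
    """Network sizes, target rates, calibration constants and ablation flags."""

    input_side: int = 7
    hidden_side: int = 28
    output_side: int = 3
    fan_in: int = 9
    epoch_steps: int = 600
    target_rate_hidden: float = 0.4      # Hz
    target_rate_output: float = 5.0 / 3.0  # Hz (0.5 spikes per 300 ms epoch)
    rate_ema: float = 0.005              # per-epoch EMA constant of the rate estimate

    # initial weights
    w_in_mean: float = 1.0
    w_in_sd_frac: float = 0.3
    w_out_init: float = 1.0

    # conductance calibration
    thr_mult_in: float = 3.0   # single-input threshold, in mean initial weights
    thr_mult_out: float = 4.0
    # hard caps, as fractions of the measured single-input spike threshold.
    # The simple task wants single-food detectors in the hidden layer (cap
    # above threshold); pair discrimination wants single inputs subthreshold
    # (cap below threshold, set per task by the training driver).
    wmax_frac_in: float = 2.0
    wmax_frac_out: float = 0.6
    conductance_divisor: str = "initial_target"  # | current_target | none

    # immediate (non-rewarded) STDP step size for input->hidden weights,
    # as a multiple of the tag magnitude K
    input_stdp_rate: float = 3.0

    # stimulus pulse driving the input layer
    stim_amp: float = 1.0
    stim_steps: int = 2

    # mechanism switches (ablations)
    use_inh_in: bool = True
    use_inh_out: bool = True
    input_stdp: bool = True
    reward_stdp: bool = True
    heterosynaptic: bool = True
    output_balancing: bool = True
    trace_normalization: bool = True
    output_sum_constant: bool = False  # substitute rule when heterosynaptic is off
    homeostatic_hidden: bool = True
    homeostatic_output: bool = True

    # fractional per-cell jitter of the neuron bias sigma (intrinsic
    # excitability heterogeneity; gives graded rather than all-or-none
    # layer recruitment under shared drive)
    hetero_sigma: float = 0.3

    ratio_max: float = 1e3
    w_floor_frac: float = 1e-6  # regrowable floor for hidden->output weights
    trace_buffer: int = 400_000
    rest_tol: float = 1e-4  # snap-to-rest tolerance of the active-set scheme
    auto_calibrate: bool = True  # rate-match conductance scales before training
    calib_epochs: int = 60

    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    stdp: StdpParams = field(default_factory=StdpParams)

    @property
    def n_input(self) -> int:
        return self.input_side ** 2

    @property
    def n_hidden(self) -> int:
        return self.hidden_side ** 2

    @property
    def n_output(self) -> int:
        return self.output_side ** 2

    @property
    def n_neurons(self) -> int:
        return self.n_input + self.n_hidden + self.n_output

    @property
    def epoch_ms(self) -> float:
        return self.epoch_steps * DT_MS

    def target_count(self, rate_hz: float) -> float:
        """Convert a target rate in Hz to expected spikes per epoch."""
        return rate_hz * self.epoch_ms / 1000.0

    def __post_init__(self):
        if self.fan_in > self.n_input:
            raise ValueError("fan_in cannot exceed the number of input cells")
        if self.conductance_divisor not in ("initial_target", "current_target", "none"):
            raise ValueError("unknown conductance_divisor mode")


@dataclass
class EpochRecord:
    """Per-epoch spike statistics and decision inputs."""

    epoch: int
    counts_input: np.ndarray
    counts_hidden: np.ndarray
    counts_output: np.ndarray
    counts_output_half: np.ndarray
    n_new_traces: int


def measure_spike_threshold(
    neuron: NeuronParams,
    synapse: SynapseParams,
    inh_ratio: float = 0.0,
    n_steps: int = 400,
    tol: float = 1e-4,
    v_rp_inh: float | None = None,
) -> float:
    """Minimal single-spike conductance increment that fires the map neuron.

    Delivers one excitatory conductance kick of size g (decaying at gamma per
    step) plus, if ``inh_ratio`` > 0, a simultaneous inhibitory kick of
    ``inh_ratio * g``, to a neuron at rest with release noise off, and bisects
    g until the neuron just spikes.
    """
    rest = rest_state(neuron)
    vrp_i = synapse.v_rp_inh if v_rp_inh is None else v_rp_inh

    def spikes(g_kick: float) -> bool:
        v, vp, isl = rest.v, rest.v_prev, rest.i_slow
        ge = gi = 0.0
        for step in range(n_steps):
            if step == 5 + synapse.inh_delay_steps:
                gi += inh_ratio * g_kick * synapse.gamma ** synapse.inh_delay_steps
            if step == 5:
                ge += g_kick
            i_syn = -ge * (v - synapse.v_rp_exc) - gi * (v - vrp_i)
            v, vp, isl, spk = _kernels.rulkov_update(
                v, vp, isl, i_syn, neuron.alpha, neuron.mu, neuron.sigma,
                neuron.beta_e, neuron.sigma_e,
            )
            if spk:
                return True
            ge *= synapse.gamma
            gi *= synapse.gamma_inh
        return False

    lo, hi = 0.0, 0.05
    while not spikes(hi):
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("no spike threshold found")
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


class Network:
    """Mutable simulation state plus the epoch-level operations.

    Use :func:`build_network` to construct one.  All heavy loops live in the
    compiled kernels; this class owns the arrays and the bookkeeping.
    """

    def __init__(self, config: NetworkConfig, rng_seed: int):
        self.config = config
        self.rng = np.random.default_rng(rng_seed)
        cfg = config
        ni, nh, no = cfg.n_input, cfg.n_hidden, cfg.n_output

        # wiring: each hidden cell picks fan_in distinct input cells
        self.in2h_idx = np.empty((nh, cfg.fan_in), dtype=np.int64)
        for h in range(nh):
            self.in2h_idx[h] = self.rng.choice(ni, size=cfg.fan_in, replace=False)
        # reverse CSR adjacency (input cell -> (hidden, slot) pairs)
        order = np.argsort(self.in2h_idx.reshape(-1), kind="stable")
        self.rev_h = (order // cfg.fan_in).astype(np.int64)
        self.rev_k = (order % cfg.fan_in).astype(np.int64)
        counts = np.bincount(self.in2h_idx.reshape(-1), minlength=ni)
        self.rev_ptr = np.zeros(ni + 1, dtype=np.int64)
        np.cumsum(counts, out=self.rev_ptr[1:])

        # initial weights: truncated-positive normal in, uniform out
        m, sd = cfg.w_in_mean, cfg.w_in_sd_frac * cfg.w_in_mean
        w = self.rng.normal(m, sd, size=(nh, cfg.fan_in))
        while (w <= 0).any():
            bad = w <= 0
            w[bad] = self.rng.normal(m, sd, size=int(bad.sum()))
        self.w_in = w
        self.w_out = np.full((nh, no), cfg.w_out_init, dtype=float)

        # per-cell targets and fixed conductance divisors
        self.wtar_h = self.w_in.sum(axis=1)
        self.wtar_o = self.w_out.sum(axis=0)
        self.div_h0 = self.wtar_h.copy()
        self.div_o0 = self.wtar_o.copy()
        self.w_i0 = self.w_out.sum(axis=1)  # output-balancing reference

        # conductance scale calibration (single-input spike threshold)
        g_thr_in = measure_spike_threshold(
            cfg.neuron, cfg.synapse,
            inh_ratio=(1.0 / cfg.thr_mult_in) if cfg.use_inh_in else 0.0,
            v_rp_inh=cfg.synapse.v_rp_inh_hidden,
        )
        g_thr_out = measure_spike_threshold(
            cfg.neuron, cfg.synapse,
            inh_ratio=(1.0 / cfg.thr_mult_out) if cfg.use_inh_out else 0.0,
            v_rp_inh=cfg.synapse.v_rp_inh_output,
        )
        self.g_scale_in = g_thr_in * cfg.fan_in * cfg.w_in_mean / cfg.thr_mult_in
        self.g_scale_out = g_thr_out * nh * cfg.w_out_init / cfg.thr_mult_out
        self.wmax_in = cfg.wmax_frac_in * cfg.thr_mult_in * cfg.w_in_mean
        self.wmax_out = cfg.wmax_frac_out * cfg.thr_mult_out * cfg.w_out_init

        # mirrored inhibition weights
        self.mirror_out = self.w_out.mean(axis=1)
        self.mirror_in = self._input_mirrors()

        # per-cell intrinsic excitability (sigma jitter) and resting states
        n = cfg.neuron
        het = cfg.hetero_sigma
        self.sig_i = n.sigma * (1.0 + het * self.rng.uniform(-1, 1, ni))
        self.sig_h = n.sigma * (1.0 + het * self.rng.uniform(-1, 1, nh))
        self.sig_o = n.sigma * (1.0 + het * self.rng.uniform(-1, 1, no))
        r = rest_state(cfg.neuron)
        self._rest = r
        self.vr_i, self.vpr_i, self.ir_i = _kernels.settle_rest_array(
            n.alpha, n.mu, self.sig_i, n.beta_e, n.sigma_e, 20_000)
        self.vr_h, self.vpr_h, self.ir_h = _kernels.settle_rest_array(
            n.alpha, n.mu, self.sig_h, n.beta_e, n.sigma_e, 20_000)
        self.vr_o, self.vpr_o, self.ir_o = _kernels.settle_rest_array(
            n.alpha, n.mu, self.sig_o, n.beta_e, n.sigma_e, 20_000)
        self.v_i = self.vr_i.copy(); self.vp_i = self.vpr_i.copy()
        self.is_i = self.ir_i.copy()
        self.v_h = self.vr_h.copy(); self.vp_h = self.vpr_h.copy()
        self.is_h = self.ir_h.copy()
        self.v_o = self.vr_o.copy(); self.vp_o = self.vpr_o.copy()
        self.is_o = self.ir_o.copy()
        self.ge_h = np.zeros(nh); self.gi_h = np.zeros(nh)
        self.ge_o = np.zeros(no); self.gi_o = np.zeros(no)
        self.gi_add_h = np.zeros(nh); self.gi_add_o = np.zeros(no)

        # spike-time rings (global steps; -1 empty)
        self.ring_i = np.full((ni, 2), -1, dtype=np.int64)
        self.ring_h = np.full((nh, 4), -1, dtype=np.int64)
        self.ring_o = np.full((no, 8), -1, dtype=np.int64)
        self.ring_i_pos = np.zeros(ni, dtype=np.int64)
        self.ring_h_pos = np.zeros(nh, dtype=np.int64)
        self.ring_o_pos = np.zeros(no, dtype=np.int64)
        self.active_i = np.zeros(ni, dtype=np.int8)
        self.active_h = np.zeros(nh, dtype=np.int8)
        self.active_o = np.zeros(no, dtype=np.int8)

        # plasticity bookkeeping
        self.store = TraceStore(lifetime=cfg.stdp.trace_lifetime)
        self.normalizer = TraceNormalizer.zeros((nh, no))
        self.rate_h = np.full(nh, cfg.target_count(cfg.target_rate_hidden))
        self.rate_o = np.full(no, cfg.target_count(cfg.target_rate_output))

        self._tr_pre = np.zeros(cfg.trace_buffer, dtype=np.int64)
        self._tr_post = np.zeros(cfg.trace_buffer, dtype=np.int64)
        self._tr_val = np.zeros(cfg.trace_buffer, dtype=np.float64)
        self._tr_epoch = np.zeros(cfg.trace_buffer, dtype=np.int64)

        self.epoch = 0
        self.step0 = 0
        self.trace_overflows = 0

    # ------------------------------------------------------------------
    def _input_mirrors(self) -> np.ndarray:
        """Mean excitatory output weight of each input cell."""
        ni = self.config.n_input
        sums = np.zeros(ni)
        np.add.at(sums, self.in2h_idx.reshape(-1), self.w_in.reshape(-1))
        counts = np.bincount(self.in2h_idx.reshape(-1), minlength=ni).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mirrors = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
        return mirrors

    def _divisors(self):
        if self.config.conductance_divisor == "initial_target":
            return self.div_h0, self.div_o0
        if self.config.conductance_divisor == "current_target":
            return self.wtar_h, self.wtar_o
        return np.ones_like(self.div_h0), np.ones_like(self.div_o0)

    def at_rest(self, tol: float = 1e-3) -> bool:
        r = self._rest
        return bool(
            max(np.abs(self.v_h - r.v).max(), np.abs(self.v_o - r.v).max()) < tol
            and max(self.ge_h.max(initial=0.0), self.ge_o.max(initial=0.0)) < tol
        )

    def reset_dynamic_state(self) -> None:
        """Return every neuron to rest and clear conductances and spike rings.

        Weights, targets and plasticity bookkeeping are untouched.
        """
        for arr, ref in ((self.v_i, self.vr_i), (self.vp_i, self.vpr_i),
                         (self.is_i, self.ir_i),
                         (self.v_h, self.vr_h), (self.vp_h, self.vpr_h),
                         (self.is_h, self.ir_h),
                         (self.v_o, self.vr_o), (self.vp_o, self.vpr_o),
                         (self.is_o, self.ir_o)):
            arr[:] = ref
        for arr in (self.ge_h, self.gi_h, self.ge_o, self.gi_o,
                    self.gi_add_h, self.gi_add_o):
            arr.fill(0.0)
        for arr in (self.ring_i, self.ring_h, self.ring_o):
            arr.fill(-1)
        for arr in (self.ring_i_pos, self.ring_h_pos, self.ring_o_pos,
                    self.active_i, self.active_h, self.active_o):
            arr.fill(0)

    def snapshot(self) -> dict:
        """Copy of the learnable state, suitable for an epoch-keyed archive.

        Keys: w_in (hidden x fan_in), w_out (hidden x n_output), wtar_h,
        wtar_o, mirror_in, mirror_out, rate_h, rate_o, epoch.
        """
        return {
            "w_in": self.w_in.copy(), "w_out": self.w_out.copy(),
            "wtar_h": self.wtar_h.copy(), "wtar_o": self.wtar_o.copy(),
            "mirror_in": self.mirror_in.copy(), "mirror_out": self.mirror_out.copy(),
            "rate_h": self.rate_h.copy(), "rate_o": self.rate_o.copy(),
            "epoch": self.epoch,
        }

    def save_weights(self, path) -> None:
        """Write the current snapshot to an .npz archive."""
        np.savez(path, **self.snapshot())

    # ------------------------------------------------------------------
    def run_epoch(self, stimulus: np.ndarray, seed: int | None = None,
                  plasticity: bool = True) -> EpochRecord:
        """Simulate one epoch of ``epoch_steps`` map steps.

        ``stimulus`` is the boolean length-49 visual-field vector; stimulated
        input cells receive the brief pulse at epoch start.  Online
        non-rewarded STDP runs inside the step loop; hidden->output pairings
        are appended to the trace store.  Output spike counts are recorded
        both for the whole epoch and restricted to the first half (the
        decision window).
        """
        cfg = self.config
        if not self.at_rest():
            logger.debug("epoch %d starts away from rest (state carryover)", self.epoch)
        div_h, div_o = self._divisors()
        if seed is None:
            seed = int(self.rng.integers(2**31))
        stim = np.ascontiguousarray(np.asarray(stimulus, dtype=np.bool_))
        tc_steps = cfg.stdp.t_c_ms / DT_MS
        window_steps = int(round(cfg.stdp.pairing_window_ms / DT_MS))
        out = _kernels.run_epoch_kernel(
            cfg.neuron.alpha, cfg.neuron.mu, self.sig_i, self.sig_h, self.sig_o,
            cfg.neuron.beta_e, cfg.neuron.sigma_e,
            cfg.synapse.gamma, cfg.synapse.gamma_inh, cfg.synapse.inh_delay_steps > 0,
            cfg.synapse.release_cv,
            cfg.synapse.v_rp_exc, cfg.synapse.v_rp_inh_hidden,
            cfg.synapse.v_rp_inh_output,
            self.g_scale_in, self.g_scale_out,
            self.v_i, self.vp_i, self.is_i,
            self.v_h, self.vp_h, self.is_h,
            self.v_o, self.vp_o, self.is_o,
            self.ge_h, self.gi_h, self.ge_o, self.gi_o,
            self.in2h_idx, self.rev_ptr, self.rev_h, self.rev_k,
            self.w_in, self.w_out, self.mirror_in, self.mirror_out,
            div_h, div_o, self.wtar_h,
            cfg.input_stdp and plasticity, cfg.reward_stdp and plasticity,
            cfg.stdp.k * cfg.input_stdp_rate, cfg.stdp.k,
            tc_steps, window_steps, self.wmax_in,
            self.ring_i, self.ring_h, self.ring_o,
            self.ring_i_pos, self.ring_h_pos, self.ring_o_pos,
            stim, cfg.stim_amp, cfg.stim_steps,
            cfg.epoch_steps, cfg.epoch_steps // 2, self.step0, self.epoch,
            cfg.use_inh_in, cfg.use_inh_out,
            self._tr_pre, self._tr_post, self._tr_val, self._tr_epoch,
            self.gi_add_h, self.gi_add_o,
            self.active_i, self.active_h, self.active_o,
            self.vr_i, self.vpr_i, self.ir_i,
            self.vr_h, self.vpr_h, self.ir_h,
            self.vr_o, self.vpr_o, self.ir_o, cfg.rest_tol,
            seed,
        )
        counts_i, counts_h, counts_o, counts_o_half, n_tr = out
        if n_tr >= cfg.trace_buffer:
            self.trace_overflows += 1
            logger.warning("trace buffer saturated in epoch %d", self.epoch)
        if cfg.reward_stdp and plasticity and n_tr:
            self.store.add_arrays(
                self.epoch, self._tr_pre[:n_tr].copy(),
                self._tr_post[:n_tr].copy(), self._tr_val[:n_tr].copy(),
            )
        rec = EpochRecord(self.epoch, counts_i, counts_h, counts_o,
                          counts_o_half, int(n_tr))
        self.step0 += cfg.epoch_steps
        return rec

    # ------------------------------------------------------------------
    def apply_reward_epoch(self, signal: RewardSignal) -> None:
        """Convert stored traces into weight changes under this epoch's signal."""
        cfg = self.config
        if not cfg.reward_stdp:
            return
        apply_reward(
            self.w_out, self.store, self.normalizer, self.w_i0, signal,
            self.epoch, cfg.stdp, w_max=self.wmax_out,
            w_floor=cfg.w_floor_frac * cfg.w_out_init,
            ratio_max=cfg.ratio_max,
            normalization_on=cfg.trace_normalization,
            balancing_on=cfg.output_balancing,
        )
        if cfg.heterosynaptic:
            sums = self.w_out.sum(axis=0)
            scale = np.where(sums > 0, self.wtar_o / np.maximum(sums, 1e-300), 1.0)
            self.w_out *= scale[np.newaxis, :]
        elif cfg.output_sum_constant:
            sums = self.w_out.sum(axis=1)
            scale = np.where(sums > 0, self.w_i0 / np.maximum(sums, 1e-300), 1.0)
            self.w_out *= scale[:, np.newaxis]

    # ------------------------------------------------------------------
    def epoch_housekeeping(self, record: EpochRecord) -> None:
        """End-of-epoch homeostasis, trace pruning and mirror refresh."""
        cfg = self.config
        a = cfg.rate_ema
        self.rate_h = (1 - a) * self.rate_h + a * record.counts_hidden
        self.rate_o = (1 - a) * self.rate_o + a * record.counts_output

        if cfg.homeostatic_hidden:
            tgt = cfg.target_count(cfg.target_rate_hidden)
            step = np.where(self.rate_h < tgt, 1.0 + cfg.stdp.d_tar,
                            np.where(self.rate_h > tgt, 1.0 - cfg.stdp.d_tar, 1.0))
            self.wtar_h *= step
            sums = self.w_in.sum(axis=1)
            self.w_in *= np.where(sums > 0, self.wtar_h / np.maximum(sums, 1e-300), 1.0)[:, None]
        if cfg.homeostatic_output:
            tgt = cfg.target_count(cfg.target_rate_output)
            step = np.where(self.rate_o < tgt, 1.0 + cfg.stdp.d_tar,
                            np.where(self.rate_o > tgt, 1.0 - cfg.stdp.d_tar, 1.0))
            self.wtar_o *= step
            if cfg.heterosynaptic:
                sums = self.w_out.sum(axis=0)
                self.w_out *= np.where(sums > 0, self.wtar_o / np.maximum(sums, 1e-300), 1.0)[None, :]

        self.store.prune(self.epoch)
        self.mirror_out = self.w_out.mean(axis=1)
        self.mirror_in = self._input_mirrors()
        self.epoch += 1


def build_network(config: NetworkConfig | None = None, rng_seed: int = 0) -> Network:
    """Construct a network with random wiring and calibrated conductances."""
    return Network(config or NetworkConfig(), rng_seed)


def calibrate_excitability(
    net: Network,
    stimulus_sampler,
    rng_seed: int = 0,
    n_epochs: int | None = None,
    rel_tol: float = 0.08,
    max_iter: int = 12,
) -> None:
    """Rate-match the conductance scales to the homeostatic targets.

    Runs short plasticity-free probe simulations under stimuli drawn from
    ``stimulus_sampler(rng)`` (the task's visual-field statistics) and bisects
    ``g_scale_in`` then ``g_scale_out`` (both monotone in the respective layer
    rate) until the mean hidden and output firing rates match their homeostatic
    target rates.  This places the network at its operating point from epoch
    one, so the slow per-epoch homeostatic drift (1 +/- D_tar) only has to
    fine-tune per-cell excitability rather than find the working regime.

    The single-input weight caps are then re-derived from the calibrated
    scales: ``w_max = wmax_frac * w_thr`` where ``w_thr`` is the synaptic
    weight whose lone presynaptic spike just fires the postsynaptic cell.
    """
    cfg = net.config
    rng = np.random.default_rng(rng_seed)
    n_epochs = n_epochs or cfg.calib_epochs
    stims = [np.asarray(stimulus_sampler(rng), dtype=np.bool_) for _ in range(n_epochs)]
    seeds = [int(rng.integers(2**31)) for _ in range(n_epochs)]

    def rates():
        net.reset_dynamic_state()
        ch = np.zeros(cfg.n_hidden, dtype=np.int64)
        co = np.zeros(cfg.n_output, dtype=np.int64)
        for stim, seed in zip(stims, seeds):
            rec = net.run_epoch(stim, seed=seed, plasticity=False)
            ch += rec.counts_hidden
            co += rec.counts_output
        return ch.mean() / n_epochs, co.mean() / n_epochs

    def solve(attr, target, get_rate):
        """Find the scale whose rate matches the target on the rising branch.

        The layer rate rises with the conductance scale up to a peak and then
        falls as balanced shunting inhibition dominates, so the usual
        monotone bracket is only valid left of the peak.
        """
        x = getattr(net, attr)

        def f(v):
            setattr(net, attr, v)
            return get_rate()

        r = f(x)
        if r > target:
            lo = x
            for _ in range(max_iter):
                lo /= 2.0
                if f(lo) < target:
                    break
            else:
                logger.info("calibration: %s stuck above target", attr)
                return
            hi = lo * 2.0
        else:
            hi, r_hi = x, r
            for _ in range(max_iter):
                cand = hi * 2.0
                r_new = f(cand)
                if r_new < r_hi:  # past the peak: no crossing exists
                    logger.info("calibration: %s peaked below target", attr)
                    setattr(net, attr, hi)
                    return
                hi, r_hi = cand, r_new
                if r_hi > target:
                    break
            else:
                logger.info("calibration: %s never reached target", attr)
                return
            lo = hi / 2.0
        for _ in range(max_iter):
            mid = np.sqrt(lo * hi)
            r = f(mid)
            if abs(r - target) <= rel_tol * target:
                return
            if r < target:
                lo = mid
            else:
                hi = mid

    tgt_h = cfg.target_count(cfg.target_rate_hidden)
    tgt_o = cfg.target_count(cfg.target_rate_output)
    solve("g_scale_in", tgt_h, lambda: rates()[0])
    solve("g_scale_out", tgt_o, lambda: rates()[1])
    net.reset_dynamic_state()

    # re-derive single-input spike-threshold weights at the calibrated scales
    m_in = float(np.mean(net.mirror_in))
    w_thr_in = _single_input_threshold_weight(
        net, net.g_scale_in, float(np.mean(net.div_h0)), m_in, cfg.use_inh_in,
        v_rp_inh=cfg.synapse.v_rp_inh_hidden)
    m_out = float(np.mean(net.mirror_out))
    w_thr_out = _single_input_threshold_weight(
        net, net.g_scale_out, float(np.mean(net.div_o0)), m_out, cfg.use_inh_out,
        v_rp_inh=cfg.synapse.v_rp_inh_output)
    net.wmax_in = cfg.wmax_frac_in * w_thr_in
    net.wmax_out = cfg.wmax_frac_out * w_thr_out
    logger.info("calibrated: g_in=%.4g g_out=%.4g w_thr_in=%.3g w_thr_out=%.3g",
                net.g_scale_in, net.g_scale_out, w_thr_in, w_thr_out)


def _fires_single_kick(neuron: NeuronParams, synapse: SynapseParams,
                       ge_kick: float, gi_kick: float, n_steps: int = 400,
                       v_rp_inh: float | None = None) -> bool:
    """Does one excitatory kick (with its delayed mirror inhibition) fire the cell?"""
    rest = rest_state(neuron)
    vrp_i = synapse.v_rp_inh if v_rp_inh is None else v_rp_inh
    v, vp, isl = rest.v, rest.v_prev, rest.i_slow
    ge = gi = 0.0
    for step in range(n_steps):
        if step == 5:
            ge += ge_kick
        if step == 5 + synapse.inh_delay_steps:
            gi += gi_kick * synapse.gamma_inh ** synapse.inh_delay_steps
        i_syn = -ge * (v - synapse.v_rp_exc) - gi * (v - vrp_i)
        v, vp, isl, spk = _kernels.rulkov_update(
            v, vp, isl, i_syn, neuron.alpha, neuron.mu, neuron.sigma,
            neuron.beta_e, neuron.sigma_e)
        if spk:
            return True
        ge *= synapse.gamma
        gi *= synapse.gamma_inh
    return False


def _single_input_threshold_weight(net, g_scale, divisor, mirror, use_inh,
                                   v_rp_inh=None):
    """Weight whose single presynaptic spike just fires the target cell.

    The accompanying mirrored inhibitory kick is held at the layer's mean
    mirror weight.  Returns inf when no finite weight fires the cell (its own
    mirror inhibition always wins); the weight cap is then inactive.
    """
    cfg = net.config
    unit = g_scale / divisor
    gi_kick = (mirror * unit) if use_inh else 0.0

    def fires(w):
        return _fires_single_kick(cfg.neuron, cfg.synapse, w * unit, gi_kick,
                                  v_rp_inh=v_rp_inh)

    hi = max(mirror, 1e-6)
    for _ in range(40):
        if fires(hi):
            break
        hi *= 2.0
    else:
        return np.inf
    lo = 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
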