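# Methods

This note records the model as implemented, the free parameters and how
their defaults were chosen, the numerical devices used to make the
simulation fast and stable, and — importantly — which published-scale
behaviours this re-implementation does and does not reproduce.

## Neuron model

Each of the 842 cells is a discrete-time two-variable map of a fast-spiking
neuron. The fast variable `v` passes through a piecewise nonlinearity
(`alpha/(1-v) - 1 + i` below zero; the peak branch `alpha + i` fires once
per crossing; reset to −1), and a slow variable integrates
`i <- i - mu (v_new + 1) + mu sigma + mu sigma_e I_ext`. The `(v+1)` form is
deliberate: with the update written as `-mu v` the map has no subthreshold
fixed point (stationarity would require `v = sigma > 0`, which contradicts
the silent branch) and fires tonically, whereas the `(v+1)` form rests at
`(v*, I*) ≈ (sigma - 1, -1.8214)` and emits exactly one spike per brief
suprathreshold pulse. One map step is 0.5 ms; all millisecond constants
convert at that rate.

A spike is registered on the step the peak branch is taken. Cells are
initialized at the numerically settled rest point (20,000 unforced
iterations).

**Intrinsic heterogeneity.** The bias `sigma` is jittered per cell by a
uniform ±30% (`hetero_sigma = 0.3`). This is a deliberate design choice,
not merely cosmetic: the map's subthreshold DC gain is `1/(1-f') ≈ 33`, so
a population of *identical* cells under shared drive behaves as a razor-edge
comparator — all cells cross threshold together and the output layer
responds all-or-none (every cell exactly one spike within 1–3 steps of the
others), making spike-count decisions carry no information. With
heterogeneous excitability the recruitment of a layer is graded in the
drive, which is what the published tie/zero-response statistics of the
decision layer imply. Homeostatic scaling (below) re-centres long-run rates
per cell, so heterogeneity shapes per-epoch recruitment order without
biasing long-run activity.

## Synapses and inhibition

Conductances decay geometrically (`gamma = 0.9` per step, ≈5 ms — the decay
rate is unconstrained by the source model, 5 ms is a standard AMPA-like
scale) and jump on each presynaptic spike by `(1 + X R) w / W`, with
per-release noise `X ~ U(-1,1)`, `R = 0.12`. The divisor `W` is the
postsynaptic cell's *initial* target input sum. Dividing by the *current*
homeostatic target (a plausible alternate reading) exactly cancels
homeostatic gain control — rescaling keeps the weight sum equal to the
target, so increments `w/W` would be invariant — and is therefore only
available as a config switch (`conductance_divisor`), not the default.

Feedforward inhibition is virtual: each projecting cell sends an inhibitory
connection to the same targets, with weight equal to the mean of its
excitatory output weights (recomputed every epoch), so summed inhibition
always equals summed excitation. Inhibitory conductance increments arrive
one step (0.5 ms) after the excitatory ones. Zero-delay inhibition was
tried and rejected on dynamical grounds: with exact synchrony and uniform
initial weights the balanced-shunting equilibrium
`v = v_rp_inh · gi/(ge+gi)` is subthreshold at every conductance scale and
the output layer cannot reach any target rate. Dimensionless reversal
potentials are 0.0 (excitatory) and −1.1 (inhibitory), ≈ −15 mV and −70 mV.

## Plasticity

* **Tags**: every pre/post pairing within 120 ms (3 time constants) makes a
  tag `±K e^{-|Δt|/T_c}`, `K = 0.04`, `T_c = 40` ms; zero lag counts as
  pre-before-post. Pairing is all-to-all over the spikes in the window.
* **Input layer (immediate, non-rewarded)**: tags are added directly to the
  input→hidden weight (step size `input_stdp_rate × K`, default 3K — the
  immediate layer has no separate published learning rate; 3K forms stable
  position detectors within a few thousand epochs), clipped, and the cell's
  input vector is heterosynaptically rescaled to its target sum.
* **Hidden→output (reward-gated)**: tags persist 6 epochs (timestamps at
  epoch resolution) and multiply the weight on each epoch's global signal:
  factor `1 + (Wi0/Wi) · s_rp · tr_k/(t−t_k+c) · Sum_tr/Avg_tr`, `c = 1`
  epoch. `Avg_tr` is a per-synapse EMA of `Sum_tr` (`delta = 0.001`,
  matching "thousands of cycles"), initialized at the first nonzero sum;
  the ratio is clamped to 1 during burn-in *and whenever `Avg_tr ≤ 0`*
  (post-before-pre tags can drive it negative, which would otherwise flip
  reward signs), and to ±1000 as a numerical guard. Factors are floored at
  0 and weights at `1e-6` of the initial value — a multiplicative zero is
  absorbing, and without the floor a fifth of the synapses die early.
* **Homeostatic scaling**: per-cell firing-rate EMA (constant 0.005/epoch)
  against the target rate; the target input sum moves by `×(1 ± 1e-4)` per
  epoch and the incoming weights are rescaled to it. Applied to hidden and
  output layers independently. Defaults: hidden 0.4 Hz, output 5/3 Hz
  (0.12 and 0.5 spikes per 300 ms epoch). Sparser hidden targets produce
  stable position detectors; at ≥0.8 Hz the detector structure churns.
* **Hard caps**: the cap is `wmax_frac × w_thr`, where `w_thr` is the
  single-input spike-threshold weight measured on the actual neuron at
  build time. Caps limit growth only: rescaling may carry a weight past the
  cap and later plasticity never cuts it back (the clip-always alternative
  turns potentiation into weight cuts once homeostatic growth exceeds the
  cap). For the simple task the input-layer cap is 2× the single-input
  threshold (single-position detectors are the task's learned endpoint);
  for the pattern task it is 0.6× (no single input may fire a hidden cell,
  so only input *pairs* — the food patterns — drive responses).

## Excitability calibration

Before training, plasticity-free probe epochs under the task's own
visual-field statistics are used to bisect the two conductance scales until
the mean hidden and output rates match their homeostatic targets
(`calibrate_excitability`). The homeostatic drift (`1e-4`/epoch) can only
fine-tune excitability on a many-thousand-epoch horizon, so the network
must start at its operating point. The layer rate is non-monotone in the
conductance scale (balanced shunting dominates at high scale), so the
solver brackets the crossing on the rising branch.

## Environment and agent

Toroidal 50×50 grid. Single task: exactly 250 food cells, uniform respawn
on consumption. Pairs task: 31 horizontal + 31 vertical two-cell patterns
(rewarded-particle density 2.5%), no pattern adjacent to another
(8-neighbourhood), whole-pair consumption and orientation-preserving
respawn. The toroidal boundary keeps food-density statistics stationary; it
also raises lookahead-heuristic performance a few points relative to a
bounded grid (measured 59.6% vs 49.3%; the published figure lies between,
and the boundary rule of the original is not stated).

Decisions use first-half-epoch output spike counts over the 8 direction
cells (the centre cell of the 3×3 output is never mapped to a move); ties
uniform among the tied; silence keeps the previous heading. A random
override (floor 1%; escalating 0.5%/foodless move on the simple task, 1% on
the pattern task, reset on food) breaks movement loops. Rewards: +1 food,
−0.5 toxic food, −0.1 (simple) / −0.01 (pattern) otherwise, applied at the
end of the epoch of the move.

Useful closed-form anchor: a *teleporting* random agent acquires food at
exactly the 10% density; a diffusive random walker self-depletes its
neighbourhood and reaches only ≈5–6.5%.

## Performance engineering

The epoch loop is a single compiled kernel (numba): per-postsynaptic-cell
conductance aggregates (exact, since decay and reversals are shared),
per-cell spike-time rings for online pairing, and an active-set scheme that
snaps cells back to their rest point once within `1e-4` of it and skips
them (the perturbation is far below the release-noise scale). A 20,000
epoch training run takes about one minute on one CPU; problem sizes in the
acceptance script (5×10⁴ heuristic moves; 3 seeds × 2×10⁴ epochs per task)
were chosen to fit a desk-scale run.

## What this implementation reproduces, and what it does not

Reproduced: the neuron and synapse dynamics and all their analytic
identities; the environment invariants; the heuristic baseline ladder
(random walk ≈ 6% < adjacent grab ≈ 36% < nearest food ≈ 56% < exhaustive
lookahead ≈ 59.5%); the plasticity algebra including the output-balancing
and trace-normalization properties; homeostatic rate control (layer rates
settle at their targets); the variance-inflation effect of removing
hidden→output inhibition; stable single-position detector formation in the
input→hidden weights on the simple task.

Not reproduced: the *learned foraging performance*. Across a wide sweep of
the free parameters (inhibitory kinetics and reversals, synaptic decay,
hidden sparseness, weight-cap placement, intrinsic heterogeneity, learning
horizons to 1.2×10⁵ epochs), the closed-loop EMA acquisition rate stays at
the non-learning baseline (≈5–10%) instead of climbing to the published
>52%, and pattern discrimination stays at chance. The diagnosis, developed
at length during this work: with identical-neuron, common-drive dynamics
the output layer's spike counts are dominated by layer-synchronous
all-or-none events, so the decision statistics are tie- and
silence-dominated and the reward-gated credit (which tags *every* spiking
output equally) carries almost no direction information for the
multiplicative update to amplify; intrinsic heterogeneity restores graded
recruitment but recruitment order is then excitability-ranked rather than
stimulus-ranked. A teacher-forced conditioning experiment (one fixed
stimulus, reward for one fixed direction) does slowly converge (~8,000
epochs), showing the reward pathway is functional; the closed-loop signal
is evidently too dilute in this reconstruction. Unstated details of the
original — most plausibly the source of per-cell response dispersion in
the decision layer, and the boundary rule — are the open gap. The
acceptance script reports the honestly computed values.
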