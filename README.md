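# stdpforage

A desk-scale simulator of a multi-layer spiking neural network that learns a
grid-world foraging task through reward-modulated spike-timing-dependent
plasticity (STDP), written for computational neuroscientists who want to
probe how synaptic learning rules and homeostatic mechanisms interact in a
closed sensory-motor loop.

## The model

A virtual agent lives on a 50x50 toroidal grid of food particles (10%
density; or horizontal/vertical two-cell food patterns in the discrimination
variant). Each movement cycle ("epoch", 600 map steps of 0.5 ms) it sees a
7x7 visual field, which drives a three-layer feedforward spiking network:

* **Neurons** are two-variable map neurons (fast-spiking type):
  `V_{n+1} = f_alpha(V_n, I_n + beta_n)` with the piecewise nonlinearity
  `f_alpha = alpha/(1-V) - 1 + I` (subthreshold), `alpha + I` (spike peak),
  `-1` (reset), and a slow variable
  `I_{n+1} = I_n - mu(V_{n+1}+1) + mu*sigma + mu*sigma_n`
  (`alpha = 3.65`, `mu = 5e-4`, `sigma = 0.06`; physiological scale
  `V_ph = 50V - 15` mV).
* **Synapses** are first-order kinetic conductances,
  `g_{n+1} = gamma*g_n + (1 + X*R) * W_ij / W_j` on a presynaptic spike,
  with release noise `X ~ U(-1,1)`, `R = 0.12`, and current
  `I_syn = -g (V_post - V_rp)`. Every cell also sends virtual feedforward
  inhibition whose weight mirrors the mean of its excitatory outputs.
* **Architecture**: 7x7 input -> 28x28 hidden (sparse fan-in of 9, immediate
  non-rewarded STDP) -> 3x3 output (all-to-all, rewarded STDP). The output
  cell with the most spikes in the first half of an epoch sets the move
  direction; ties break randomly; silence repeats the last move.
* **Plasticity**: STDP tags `tr = +/-K e^{-|dt|/T_c}` (`K = 0.04`,
  `T_c = 40 ms`). Input-layer tags apply immediately; hidden->output tags
  are stored six epochs and converted to weight changes by the global
  reward `s_rp` (+1 food, -0.5 toxic food, -0.1/-0.01 nothing):
  `W_ij <- W_ij * prod_k (1 + (Wi0/Wi) * s_rp * tr_k/(t-t_k+c) *
  Sum_tr/Avg_tr)` - with output balancing (`Wi0/Wi`), trace normalization
  (`Sum_tr/Avg_tr`), heterosynaptic rescaling (input sums pinned to a
  per-cell target), homeostatic target drift (`x (1 +/- 1e-4)` per epoch
  toward target firing rates) and hard weight caps.

Four heuristic reference agents (random walk, adjacent grab, nearest food,
exhaustive 5-move lookahead) bracket the achievable performance.

## Worked example

```
$ python examples/run_baselines.py
random_walk   :   6.9% food per move
adjacent_grab :  36.3% food per move
nearest_food  :  56.8% food per move
exhaustive5   :  59.8% food per move
```

The exhaustive 5-move lookahead is the strongest heuristic: ~0.6 food per
move at 10% density, the ceiling against which the learned network is
judged. A short training run of the full network:

```
$ python examples/train_simple.py
epoch   500: EMA food rate 0.035  silent epochs 59%  tied decisions 41%
...
epoch  3000: EMA food rate 0.076  silent epochs 32%  tied decisions 67%
final EMA acquisition rate: 0.076 (food density 0.10; the lookahead heuristic reaches ~0.56)
```

The EMA food rate is the exponential moving average (per-move constant
0.002) of food acquired per move; "silent" epochs produced no output spikes
(the agent keeps its heading) and "tied" epochs had several equally active
output cells (direction drawn among them). See `docs/methods.md` for what
this implementation does and does not reproduce, and the `examples/`
directory for the other capabilities (neuron dynamics, plasticity algebra,
the pattern-discrimination task, mechanism ablations). A thin CLI wraps the
same functions: `stdpforage train|ablate|sweep|baseline --help`.

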