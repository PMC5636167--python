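"""Heuristic reference agents on the single-food environment.

Runs the four hand-coded policies for 5,000 moves each and prints their
food-per-move rates; the ordering (random walk < adjacent grab < nearest
food < exhaustive lookahead) brackets what the learned network can achieve.
"""
import stdpforage as sf

for kind in ("random_walk", "adjacent_grab", "nearest_food", "exhaustive5"):
    res = sf.run_baseline(kind, n_moves=5_000, rng_seed=0)
    print(f"{kind:14s}: {100 * res.acquisition_rate:5.1f}% food per move")
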