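"""Pattern-discrimination task: horizontal pairs rewarded, vertical punished.

Trains for 4,000 epochs and prints the fraction of rewarded ("good") food
among all food acquired - the discrimination accuracy.
"""
import numpy as np
import stdpforage as sf

result = sf.train(task="pairs", n_epochs=4_000, rng_seed=1)
m = result.metrics
good = int((m.outcome == 1).sum())
bad = int((m.outcome == -1).sum())
print(f"food acquired: {good} rewarded (horizontal), {bad} punished (vertical)")
print(f"good-food fraction, whole run: {good / max(good + bad, 1):.2f}")
print(f"good-food fraction, last 2000 moves: {m.discrimination_accuracy():.2f}")
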