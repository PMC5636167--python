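"""Trace algebra and the reward-gated weight update on a toy synapse set.

Creates one eligibility tag, applies a reward and a punishment, and shows the
multiplicative factors (1 + s_rp * tr) and the heterosynaptic sum restore.
"""
import numpy as np
import stdpforage as sf
from stdpforage.plasticity import TraceNormalizer, TraceStore

params = sf.StdpParams()
print("tag for zero-lag pre-before-post pair:", sf.stdp_trace_value(10, 10, params))
print("tag for 40 ms lag (one time constant):", round(sf.stdp_trace_value(0, 40, params), 6))

for s_rp, label in [(1.0, "reward +1"), (-0.5, "punishment -0.5")]:
    w = np.full((3, 2), 0.5)
    store = TraceStore()
    store.add(sf.Trace(pre_index=0, post_index=0, value=0.04, t_k=0))
    norm = TraceNormalizer.zeros((3, 2))
    norm.avg_tr[0, 0] = 0.04
    norm.initialized[0, 0] = True
    sf.apply_reward(w, store, norm, w.sum(axis=1), sf.RewardSignal(s_rp), 0, params)
    print(f"{label}: tagged weight 0.5 -> {w[0, 0]:.4f} "
          f"(factor {w[0, 0] / 0.5:.3f}); untagged stay {w[1, 1]}")

w = np.array([2.0, 2.0, 1.0])
print("heterosynaptic rescale of", w, "to target 2.0 ->",
      sf.heterosynaptic_rescale(w, 2.0), "(sum restored exactly)")
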