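"""Effect of removing hidden->output feedforward inhibition.

Without inhibition to the output layer, per-epoch output activity swings
between silence and layer-wide bursts: the variance of the per-epoch output
spike count inflates relative to the intact network.
"""
import numpy as np
import stdpforage as sf

rng = np.random.default_rng(0)
stims = rng.random((150, 49)) < 0.12
for flag, label in [(True, "inhibition intact"), (False, "no output inhibition")]:
    net = sf.build_network(sf.NetworkConfig(use_inh_out=flag), rng_seed=4)
    counts = [net.run_epoch(s, plasticity=False).counts_output.sum() for s in stims]
    print(f"{label:22s}: mean {np.mean(counts):5.2f}  variance {np.var(counts):7.2f}")
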