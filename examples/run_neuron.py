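"""Map-neuron basics: silent rest, single spike per stimulus pulse, mV scale.

Builds one fast-spiking map neuron, verifies it is quiescent, drives it with
the standard 2-step pulse and prints the spike it evokes.
"""
import stdpforage as sf

params = sf.NeuronParams()
state = sf.rest_state(params)
print(f"resting state: v = {state.v:.4f} ({sf.v_to_mv(state.v):.1f} mV), "
      f"i_slow = {state.i_slow:.4f}")

quiet = state
n_spikes = 0
for _ in range(10_000):
    quiet = sf.rulkov_step(quiet, params)
    n_spikes += quiet.spiked
print(f"spikes over 10,000 unforced steps: {n_spikes} (the rest point is silent)")

spike_steps = []
for step in range(1000):
    state = sf.rulkov_step(state, params, i_ext=1.0 if step < 2 else 0.0)
    if state.spiked:
        spike_steps.append(step)
print(f"2-step pulse of amplitude 1.0 evokes spikes at steps {spike_steps} "
      f"(exactly one spike, ~{spike_steps[0] * 0.5:.1f} ms after pulse onset)")
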