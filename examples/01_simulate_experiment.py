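"""Simulate a holographic ensemble-stimulation mapping experiment.

Builds a random 100-neuron circuit (10% connected), designs 10-target
ensemble stimuli over three laser powers, and synthesizes 45-ms voltage-clamp
trial windows at 20-kHz resolution.
"""

import numpy as np

from holomap.nwd import integrate_charge
from holomap.simulate import (NoiseConfig, SimConfig, design_stimulus,
                              sample_ground_truth, simulate_trialwise)

rng = np.random.default_rng(0)
cfg = SimConfig(n_neurons=100, connect_rate=0.1)
truth = sample_ground_truth(cfg, rng)
design = design_stimulus(100, ensemble_size=10, n_sweeps=20, rng=rng)
record = simulate_trialwise(truth, design, NoiseConfig(spont_rate=1.0), rng)

print(f"circuit: {truth.connected.sum()} connected neurons "
      f"({truth.strong.sum()} strong), weights "
      f"{truth.weights[truth.connected].min():.0f}-"
      f"{truth.weights[truth.connected].max():.0f} pA*ms")
print(f"design: {design.n_trials} trials, powers {design.power_set} mW, "
      f"{len(design.holograms)} holograms")
y = integrate_charge(record.traces)
print(f"raw trace charges: median {np.median(y):.0f} pA*ms, "
      f"95th pct {np.percentile(y, 95):.0f} pA*ms")
print(f"{record.spont_times.size} spontaneous PSCs landed in the recording")
# The charge of a trial reflects which targeted neurons actually spiked;
# spike probability rises with laser power, so high-power trials carry more
# synaptic charge on average.
for p in design.power_set:
    sel = design.trial_power() == p
    print(f"  mean charge at {p:.0f} mW: {y[sel].mean():8.1f} pA*ms")
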