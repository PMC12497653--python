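"""Infer synaptic connectivity with CAVIaR on a simulated experiment.

Runs the model-based compressed-sensing engine on charge measurements from
a 10-Hz ensemble experiment (at this slow rate trial windows do not overlap,
so raw-trace charges are usable without demixing) and compares the inferred
map with the ground truth.
"""

import warnings

import numpy as np

from holomap import caviar
from holomap.nwd import integrate_charge
from holomap.postprocess import compare_maps
from holomap.simulate import (NoiseConfig, SimConfig, design_stimulus,
                              sample_ground_truth, simulate_trialwise)

warnings.filterwarnings("ignore")
rng = np.random.default_rng(1)
n = 100
truth = sample_ground_truth(SimConfig(n_neurons=n), rng)
design = design_stimulus(n, ensemble_size=10, n_sweeps=45, stim_rate=10.0, rng=rng)
record = simulate_trialwise(truth, design, NoiseConfig(spont_rate=1.0), rng)
y = integrate_charge(record.traces)

result = caviar.fit(y, design, None, np.random.default_rng(2), traces=record.traces)
cmp = compare_maps(truth.weights, result.weights)

print(f"fit: {result.n_iter} iterations, converged={result.converged}")
print(f"connected: {int(result.connected.sum())} inferred / "
      f"{int(truth.connected.sum())} true")
print(f"R^2={cmp.r2:.3f}  precision={cmp.precision:.2f}  recall={cmp.recall:.2f}")
print(f"estimated spontaneous event rate per trial: {result.state.lam_spont:.3f}")
print("\n  neuron   true w   estimated w   spike rate @ max power")
for nn in np.flatnonzero(truth.connected | result.connected):
    curve = result.curves[nn]
    fmax = curve.at_max_power() if curve is not None else 0.0
    print(f"  {nn:6d} {truth.weights[nn]:8.0f} {result.weights[nn]:13.0f} {fmax:12.2f}")
# Neurons are declared connected only if their isotonic power curve clears
# the minimum spike rate at maximum laser power; weights are posterior-mean
# charge transfers in pA*ms.
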