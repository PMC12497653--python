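"""Leave-one-hologram-out cross-validation of inferred connectivity.

For every hologram, the model is refit without that hologram's trials and
asked to predict the mean postsynaptic response to the never-seen
stimulation pattern at each laser power, sampling over posterior weight,
power-curve and spike uncertainty.  High pooled R^2 means the inferred
connectivity generalizes to novel stimulation patterns.

Demixing is part of this pipeline: it removes the spontaneous PSCs and
correlated noise that would otherwise corrupt both the held-out trial
means (only a few repeats per hologram and power) and the trial-masking
statistic.  A compact network is trained here from scratch, so expect the
whole example to take a few minutes.
"""

import warnings

import numpy as np

from holomap.nwd import (NWDConfig, UNet1D, demix, integrate_charge,
                         make_training_set, train)
from holomap.postprocess import loho_cv
from holomap.simulate import (NoiseConfig, SimConfig, design_stimulus,
                              sample_ground_truth, simulate_trialwise)

warnings.filterwarnings("ignore")

print("training a compact demixing network ...")
cfg = NWDConfig(epochs=6, n_train=1500, seed=0)
rng = np.random.default_rng(cfg.seed)
data = make_training_set(cfg, cfg.n_train, rng)
model = UNet1D(cfg, rng)
train(model, data.inputs, data.targets, cfg, rng)

rng = np.random.default_rng(3)
n = 100
truth = sample_ground_truth(SimConfig(n_neurons=n), rng)
# repeated-hologram design: 3 distinct partitions, each hologram presented
# across sweeps at random powers
design = design_stimulus(n, ensemble_size=10, n_sweeps=30, fixed_holograms=True,
                         n_partitions=3, stim_rate=10.0, rng=rng)
record = simulate_trialwise(truth, design, NoiseConfig(spont_rate=1.0), rng)
demixed = demix(model, record.traces)
y = integrate_charge(demixed)

res = loho_cv(y, design, None, np.random.default_rng(5), traces=demixed,
              n_samples=500)
print(f"{len(np.unique(res.hologram))} held-out holograms, "
      f"{len(res.observed)} (hologram, power) cells")
print(f"pooled predictive R^2 = {res.pooled_r2:.3f}")
for p, r2 in sorted(res.per_power_r2.items()):
    print(f"  R^2 at {p:.0f} mW: {r2:.3f}")
print("observed vs predicted mean responses (first 8 cells):")
for o, pr in list(zip(res.observed, res.predicted))[:8]:
    print(f"  observed {o:8.1f}   predicted {pr:8.1f}  pA*ms")
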