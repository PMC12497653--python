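# holomap

Model-based compressed sensing of synaptic connectivity from holographic
ensemble-stimulation electrophysiology.

## The problem

Two-photon holographic optogenetics can photostimulate ensembles of
candidate presynaptic neurons while a postsynaptic neuron is recorded in
whole-cell voltage clamp.  Mapping a circuit then means recovering, from
the evoked postsynaptic currents (PSCs), the vector of synaptic weights
**w** ∈ ℝᴺ — the charge transfer (pA·ms) each candidate contributes per
transmitted spike.  Stimulating R-neuron ensembles at up to 50 Hz tests
many candidates per second, but the measurements become confounded: PSCs
from adjacent trials overlap the 45-ms recording window, spontaneous
synaptic events mimic responses, and presynaptic spiking is stochastic and
power-dependent.  `holomap` implements the full analysis stack for this
setting:

- **`holomap.simulate`** — biophysically structured simulator of mapping
  experiments (double-exponential PSC kernels, sigmoid optogenetic power
  curves, inverse-square latency law, log-normal gain noise, GP/AR(1)
  electrode noise, spontaneous PSC trains; independent trial windows or one
  continuous 20-kHz recording re-windowed into overlapping trials).
- **`holomap.nwd`** — neural waveform demixing: a 1-D U-Net (NumPy, four
  contraction + four expansion blocks) trained on synthetic PSC mixtures to
  isolate the PSC initiated in the admissible window after each stimulus;
  charge integration y_k = ∫ c_k(t) dt collapses each demixed trial to one
  measurement.
- **`holomap.caviar`** — CAVIaR, coordinate-ascent variational inference
  with isotonic regularization for the hierarchical model

      y_k ~ Normal(wᵀ s_{:,k} + z_k, σ²),
      s_nk ~ Bernoulli(sigmoid(φ⁰_n I_nk − φ¹_n)),
      w_n ~ Normal(u, b²),  φ_n ~ TruncNormal(v, L),  σ⁻² ~ Gamma(t_sh, t_ra),

  inferring weights, per-trial presynaptic spikes, per-neuron optogenetic
  power curves, observation noise and per-trial spontaneous currents z_k.
  Neurons whose pool-adjacent-violators (PAVA) isotonic power curve at
  maximum laser power falls below a minimum spike rate — adaptively raised
  by the estimated spontaneous event rate — are disconnected.
- **`holomap.postprocess`** — post hoc false-negative rescue from the
  spontaneous-current estimate, non-negative ridge recovery of canonical
  PSC waveforms, connectivity-map metrics (R², precision, recall), and
  leave-one-hologram-out cross-validation.
- **`holomap.baselines`** — CoSaMP (generic compressed sensing on the
  binary stimulation matrix) and a spike-and-slab variational ablation
  without the isotonic/spontaneous machinery.
- **`holomap.benchmark` / `holomap.cli`** — accuracy-versus-stimulation-
  time benchmark driver and a thin `holomap` command-line wrapper
  (simulate / nwd-train / demix / fit / waveforms / compare / loho /
  baseline / benchmark) over HDF5 experiment containers.

## Worked example

`examples/03_map_connectivity.py` simulates a 100-neuron circuit mapped
with 10-target ensembles at 10 Hz and runs CAVIaR on the trial charges:

```
fit: 24 iterations, converged=True
connected: 8 inferred / 10 true
R^2=0.966  precision=1.00  recall=0.80
estimated spontaneous event rate per trial: 0.009

  neuron   true w   estimated w   spike rate @ max power
       3     1038          1123         1.00
      13      519           603         1.00
      24      152           211         0.96
      31      297           342         0.99
      43      132             0         0.31
      47      331           404         1.00
      70      216             0         0.87
      79      272           309         0.99
      89      830           779         1.00
      92      762           767         1.00
```

R² compares true and estimated weight vectors over all 100 candidates;
precision/recall score the binarized map.  The two weakest synapses were
rejected — neuron 43's inferred spike rate at maximum power (0.31) fell
below the plausibility threshold, and neuron 70's estimated charge fell
below the noise floor — false negatives of the kind the post hoc rescue
scan targets.  The other examples cover the simulator, demixer training,
baseline comparisons and leave-one-hologram-out validation.

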