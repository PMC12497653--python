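# Methods

This note documents the models implemented in `holomap`, the choices made
where the underlying methods left details open, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Two-photon holographic optogenetics can stimulate ensembles of candidate
presynaptic neurons while a postsynaptic neuron is held in voltage clamp.
Each 45-ms trial window (900 samples at 20 kHz, stimulus onset at sample
100) records the evoked postsynaptic current (PSC) plus confounds: PSCs
bleeding in from adjacent trials at high stimulation rates, spontaneous
synaptic events, and electrode noise.  The goal is the synaptic weight
vector w — per-neuron charge transfer (pA·ms) evoked by one transmitted
presynaptic spike — for hundreds to thousands of candidates, as quickly as
possible.

## Demixing network (NWD)

A sequential 1-D U-Net maps a raw trial window to the clean PSC component
initiated in the admissible window (default 3–12 ms after the stimulus).
Four contraction blocks (2× temporal decimation → convolution → batch norm
→ ReLU) and four expansion blocks (transposed convolution → batch norm →
ReLU → 2× linear interpolation) with skip connections at matching
resolutions.  Implementation notes:

- The network is pure NumPy with hand-written backpropagation (verified
  against finite differences in the test suite) and SGD with momentum 0.9,
  batch 64, learning rate 0.01 with a step decay for the final epochs.
- 900 samples are right-padded to 912 (the smallest multiple of 2⁴) and
  cropped on output.
- A transposed convolution with stride 1 is the adjoint of a stride-1
  convolution and spans the same operator class, so the expansion blocks
  reuse the convolution layer.
- Convolutions are translation-equivariant, but the demixing task is
  defined in absolute window time; a fixed linear time-ramp channel is
  stacked onto the input trace so the network can reference position.
- Inputs are normalized per trace by their maximum absolute amplitude
  (floored at 1 pA); the factor is stored and inverted on output.
- After the forward pass the output is forced to decay monotonically after
  sample `t_monotone` (default 424 ≈ end of the initiation window plus
  three rise-time constants) via the recursion N_t = min(N_t, N_{t-1}).

Training data are synthetic: each example sums an independent number of
PSC templates for the previous trial(s) (onsets in [-45, 2] ms relative to
window start), the target trial (onsets in the initiation window) and the
next trial(s) (onsets after it), with double-exponential kinetics drawn
from an excitatory or inhibitory preset, log-uniform charges in
[15, 1000] pA·ms, RBF-kernel Gaussian-process noise and white noise whose
variance is itself uniform-random.  10% of examples are pure noise with an
all-zero target, teaching the network to zero out empty windows.  The
regression target is the clean target-trial component; the loss is MSE.

## Experiment simulator

Ground-truth circuits draw exactly ⌈αN⌉ connected neurons (α = 0.1 by
default); 20% are "strong" with weights uniform on [500, 1500] pA·ms and
80% "weak" with right-shifted exponential weights 100 + Exp(250) pA·ms —
matching the charge range implied by tens-to-hundreds-of-pA PSC amplitudes
with ~5–10 ms decay constants, with a weak tail that deliberately straddles
the detection limit.  Per-neuron spike generation is a linear–nonlinear–
Bernoulli model sigmoid(φ⁰I − φ¹) with φ⁰ ~ U(0.17, 0.37) mW⁻¹ and
φ¹ ~ U(4, 11): almost every cell is reliably excitable at the maximum power
(60 mW) while spiking at 30 mW spans ~0.05–0.95 — the regime in which
power-curve inference matters and spike-agnostic regression is biased.
Spike latencies are right-shifted gamma with mean 1 + 5400/I² ms
(inverse-square power dependence).  Trial-to-trial PSC gain is log-normal
with σ = 0.15 (median gain exactly 1).  Spontaneous PSC amplitudes mirror
the evoked weight distribution (20% strong-like), because spontaneous
events are real synaptic releases and their ability to mimic connections
is precisely the confound of interest.

Two modes share this latent structure.  Trial-wise mode synthesizes
independent windows (GP noise with σ²=2 pA², 1-ms lengthscale, plus 2-pA
white noise; at most one spontaneous PSC per window with probability
rate × 45 ms).  Continuous mode builds one long 20-kHz trace by placing
kernels at their onset bins, adds an AR(1) noise process (γ = 0.95,
stationary sd 2 pA) and a Poisson spontaneous train, then extracts
overlapping 900-sample windows; at 50 Hz adjacent windows share 500
samples, which is the confound regime the demixer is trained for.

Stimulus designs partition all targets into R-neuron holograms fresh every
sweep (remainder targets form a smaller final hologram), with a single
per-trial power drawn from {30, 45, 60} mW.  For leave-one-hologram-out
validation a small number of partitions (default 3) is cycled so that each
hologram repeats across powers and each neuron appears in several distinct
holograms — without this, holding out a hologram would remove every trial
of its targets and the held-out prediction would be undefined.

## CAVIaR inference engine

Observation model: y_k ~ Normal(wᵀs_{:,k} + z_k, σ²) where y_k is the
demixed-trace charge integral, s are Bernoulli spikes with sigmoid
power-curve priors φ_n ~ Normal(v, L) truncated to the positive quadrant,
w_n ~ Normal(u, b²) and σ⁻² ~ Gamma(t_sh, t_ra).  The spontaneous current
z_k is part of the trial mean, so all conditional updates subtract it from
y_k.  The variational posterior factorizes as Gaussian weights ×
independent Bernoulli spikes × truncated-normal sigmoid coefficients ×
gamma noise precision.

Updates per outer iteration, in order: per-neuron spike updates over all
trials (randomized neuron order), each followed by the isotonic
plausibility check; the conjugate weight block update; per-neuron Laplace
updates of the sigmoid coefficients (Newton with log barrier sharpened
10× → 100× → 1000×, backtracking line search, covariance from the inverse
Hessian at the mode); the conjugate noise update; the spontaneous-current
update.  The spike-update prior term is a Monte-Carlo average of the
log-odds over the truncated posterior marginals of φ (for the logistic
link this expectation is linear in φ, so the average converges fast; M =
100 by default).  The likelihood term couples the trial residual with the
posterior weight mean and variance; the quadratic self-term
−(μ_n² + β_n²)/2σ² enters as a penalty, as the coordinate-ascent
derivation of the stated model requires (verified against a brute-force
two-state evidence-bound oracle in the tests).

### Two-phase schedule

Plain coordinate ascent must reach a stable operating point before the
robustness machinery can judge anything.  At initialization the noise-scale
estimate equals the raw signal scale and contracts geometrically over the
first iterations; a power curve evaluated against a still-inflated noise
scale would condemn any synapse that has not yet accumulated evidence, and
a residual evaluated then would label half the data "spontaneous".  Fit
therefore runs in two phases:

- **Phase 1** — spike, weight, sigmoid-coefficient and noise updates only.
  The spike update uses the point-estimate likelihood coupling (β² = 0):
  with the exact term, a neuron whose spike posterior is still near the
  prior has posterior weight variance near the (large) prior variance, the
  variance penalty pushes its spike probabilities further down, which
  inflates the variance again — a death spiral that permanently loses
  mid-sized true synapses.
- **Phase 2** (once the weight posterior and noise scale stabilize, or
  after `burn_in` = 15 iterations) — the exact spike update, the isotonic
  plausibility rule applied immediately after each neuron's spike update,
  and the spontaneous-current update.

Convergence: max |Δμ| < 2×10⁻³ · max|μ| with at least two phase-2
iterations (a tighter 10⁻⁵ criterion is unreachable because the
Monte-Carlo prior term jitters the spike posteriors at a larger scale).

### Plausibility, masking, spontaneous currents

Per-power mean spike posteriors are fit by a weighted pool-adjacent-
violators isotonic regression (weights = trial counts, so pooled solutions
minimize the trial-level objective).  A neuron is disconnected — weights
and spike posteriors hard-zeroed, permanently — if the fitted curve at the
maximum power falls below θ_PAVA + λ_spont, or if its posterior mean weight
does not exceed the posterior observation-noise sd (currents are
magnitudes, so non-positive weights only fit noise; and a per-spike charge
below the noise floor is indistinguishable from noise on any trial — spike
posteriors aligned with noise excursions would otherwise keep such
micro-weights hovering at the threshold).  The same noise floor enters the
spike-and-slab baseline's post hoc weight gate.  θ_PAVA defaults to 0.4, the inhibitory-mapping value matching the
simulator's default kinetics preset; 0.3 is appropriate for excitatory
mapping.

Trial masking scores each demixed trace by its lag-1 sample
autocorrelation; traces with standard deviation below 0.1 pA are scored 0
(autocorrelation of a numerically constant trace is undefined, and demixed
pure-noise windows are near-zero — the floor is what makes masking
effective after demixing).  Masked trials have spike posteriors pinned to
zero.  τ_min defaults to 0.5, which masks ≥95% of pure-noise windows in
the calibration test.

Spontaneous currents: positively rectified residuals e_k are
soft-thresholded with penalty γ, shrunk (geometric steps, then bisection
for the largest satisfying value) until the residual norm is at most
ε = 0.05 of the observed norm.  γ never falls below twice the posterior
noise sd: residuals at the noise scale are not events, and without the
floor the loop degenerates to z = e whenever the ε criterion is
unattainable.  z is forced to zero on masked trials and on trials whose
total inferred spike probability exceeds θ_orthog; with 10–20-target
ensembles the prior-level spike probabilities of a few connected targets
sum to ~0.2–0.3 on event-free trials, so θ_orthog = 0.5 (rather than a
value near zero appropriate for single-target designs).  λ_spont is the
fraction of trials carrying a nonzero z.

Other defaults: u = 0; b² = (2 × 95th percentile of |y|)²; vague gamma
prior t_sh = t_ra = 10⁻²; φ prior v = (0.02, 4.5), L = diag(0.05², 2²).
The φ prior is deliberately conservative — prior spike probability ≈ 0.16
at 60 mW, below θ_PAVA — so that neurons with no likelihood support fail
the plausibility rule; the cost is a mild shrinkage of posterior power
curves below 1 for perfectly reliable cells, visible as a small downward
bias in posterior-predictive response estimates.  The Laplace update for
φ_n sums over targeted trials only: untargeted trials carry forced-zero
spike posteriors and would otherwise drag the intercept to the boundary.

## Post-processing

The false-negative scan greedily revisits disconnected neurons in order of
their coincident spontaneous events (z_k > 0 on trials where the neuron
was stimulated), reconnects a neuron when the isotonic coincidence rate at
maximum power clears θ_PAVA + λ_spont, summarizes its posterior by the
sample statistics of the coincident charges, and consumes those events so
one spontaneous train cannot resurrect several co-targeted neurons.

Canonical waveforms solve the non-negative ridge problem
min_{R≥0} ‖C − ΛᵀR‖²_F + γ‖R‖²_F by accelerated projected gradient
(tolerance 10⁻⁸); using the inferred spike matrix instead of the raw
stimulation matrix keeps failure trials from diluting the waveforms.

Map comparison reports the coefficient of determination over full weight
vectors (scikit-learn's r2_score) and precision/recall on binarized
connectivity (nonzero weight ⇔ connected, matching the hard disconnect
rule).  Leave-one-hologram-out cross-validation refits the model without
each hologram and predicts held-out mean responses from 500 posterior
samples per (hologram, power), adding the expected spontaneous
contribution; per-hologram RNG streams make the result independent of
hold-out order.

## Scaled benchmark conditions

The headline experiments are reproduced at population sizes chosen for a
single CPU: 200 candidates (20-target ensembles, 50 Hz, 30 s ≈ 150
stimulations/neuron) for the speed and robustness runs, 300 candidates
(10-target, 30 Hz, 900 trials) for systematic parameter recovery, 150
candidates for the long spike-and-slab degradation run, and 100 candidates
for cross-validation.  The CoSaMP comparison keeps the full 1,000-candidate
geometry because a greedy least-squares baseline is cheap at that size.
Test-suite networks train on 3,500 examples for 14 epochs; the acceptance
script uses 4,000 examples for 16 epochs.  Demixing quality keeps
improving with the full budget (50,000 examples, thousands of epochs), so
the charge-integral noise floor here (~50–90 pA·ms rms on confounded
windows) — and with it the weak-weight detection limit — is conservative.

## Known limitations

- The observation model is homoscedastic, but trial-gain variability makes
  residuals scale with evoked amplitude; very small weights co-stimulated
  with strong synapses can occasionally absorb gain noise (bounded by the
  plausibility rule, and negligible above ~0.9 precision in the benchmark
  regimes).
- At high spontaneous rates the simulator's within-initiation-window
  events are indistinguishable from evoked PSCs by construction; no
  demixer can remove them, so robustness there comes entirely from the
  adaptive plausibility threshold.
- The generator emulates kinetics, latency laws, gain noise, correlated
  and autoregressive noise and spontaneous trains, but not photocurrent
  artifacts, access-resistance drift, dendritic filtering or short-term
  plasticity; passing benchmarks therefore demonstrate algorithmic
  correctness under the stated model, not performance on every
  experimental pathology.
- Synthetic benchmarks at reduced population size slightly favor all
  methods (more data per candidate in the same simulated time); relative
  orderings between methods were stable across the sizes tested.
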