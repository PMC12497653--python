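"""Simulator of holographic ensemble-stimulation circuit-mapping experiments.

Generates ground-truth circuits (synaptic weights, per-neuron opsin power
curves, PSC kinetics, power-dependent spike latencies) and synthetic
voltage-clamp recordings at 20-kHz resolution, either as independent 45-ms
trial windows ("trial-wise" mode) or as one long continuous recording that is
subsequently re-windowed ("continuous" mode, which reproduces the overlap of
adjacent trials at high stimulation rates).

All currents are stored as non-negative magnitudes (pA); whether they are
excitatory or inhibitory is a labelling concern only, since opsin expression
restricts each experiment to a single presynaptic cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .kernels import DT_MS, STIM_ONSET, TRIAL_SAMPLES, PSCTemplate


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Ground-truth circuit parameters.

    Weights are synaptic charge transfers in pA*ms.  The connected population
    splits into a strongly connected minority (uniform weights) and a weakly
    connected majority (right-shifted exponential weights), mirroring the
    long-tailed weight distributions seen in cortical slice recordings.
    Sigmoid (power-curve) coefficients phi = (phi0, phi1) give per-neuron
    spike probability sigmoid(phi0 * I - phi1) at laser power I (mW).
    Spike latencies follow a right-shifted gamma law whose mean obeys the
    inverse-square dependence on power characteristic of two-photon
    excitation: E[delta] = latency_min + latency_alpha / (latency_beta * I^2).
    """

    n_neurons: int = 300
    connect_rate: float = 0.1
    strong_fraction: float = 0.2
    w_min_strong: float = 500.0
    w_max_strong: float = 1500.0
    w_mean_weak: float = 250.0
    w_min_weak: float = 100.0
    phi0_bounds: tuple = (0.17, 0.37)   # 1/mW
    phi1_bounds: tuple = (4.0, 11.0)
    tau_r_bounds: tuple = (0.8, 2.0)    # ms
    tau_diff_bounds: tuple = (4.0, 10.0)  # tau_d = tau_r + tau_diff
    latency_alpha: float = 5400.0       # gamma shape = alpha / I^2
    latency_beta: float = 1.0           # gamma rate, 1/ms
    latency_min: float = 1.0            # ms
    sigma_mult: float = 0.15            # log-normal sd of trial-to-trial gain

    def validate(self):
        if not 0 < self.connect_rate < 1:
            raise ValueError("connect_rate must lie in (0, 1)")
        if self.connect_rate * self.n_neurons < 1:
            raise ValueError("connectivity rate too low: no connected neurons")
        if self.w_max_strong < self.w_min_strong:
            raise ValueError("inverted strong-weight bounds")
        if min(self.phi0_bounds + self.phi1_bounds) <= 0:
            raise ValueError("sigmoid coefficient bounds must be positive")
        if self.w_min_weak < 0 or self.w_mean_weak <= 0:
            raise ValueError("invalid weak-weight parameters")


@dataclass
class NoiseConfig:
    """Recording-noise and spontaneous-activity parameters.

    ``sigma_scale``/``ell_gp`` parameterize the RBF-kernel Gaussian-process
    noise used in trial-wise mode (variance scale in pA^2, lengthscale in ms);
    ``sigma_noise`` is the i.i.d. electrode noise s.d. in pA; ``gamma_ar`` the
    AR(1) coefficient used for the continuous mode; ``spont_rate`` the
    spontaneous PSC rate in Hz.  Spontaneous amplitudes (charges, pA*ms) are
    right-shifted exponential.
    """

    sigma_scale: float = 2.0
    ell_gp: float = 1.0
    sigma_noise: float = 2.0
    gamma_ar: float = 0.95
    spont_rate: float = 1.0
    spont_amp_mean: float = 250.0
    spont_amp_min: float = 100.0
    spont_strong_fraction: float = 0.2
    spont_strong_range: tuple = (500.0, 1500.0)

    def validate(self):
        if not 0 < self.gamma_ar < 1:
            raise ValueError("gamma_ar must lie in (0, 1)")
        if self.sigma_scale < 0 or self.ell_gp <= 0 or self.sigma_noise < 0:
            raise ValueError("noise scales must be non-negative")
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class GroundTruth:
    """Latent circuit used to generate an experiment."""

    weights: np.ndarray          # (N,) charge transfer, 0 for unconnected
    connected: np.ndarray        # (N,) bool
    strong: np.ndarray           # (N,) bool
    phi: np.ndarray              # (N, 2) sigmoid coefficients (phi0, phi1)
    tau_r: np.ndarray            # (N,) ms
    tau_d: np.ndarray            # (N,) ms
    config: SimConfig = None

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def spike_probability(self, power) -> np.ndarray:
        """Per-neuron spike probability at laser power(s) ``power``."""
        power = np.asarray(power, dtype=float)
        return sigmoid(self.phi[:, [0]] * power[None, :] - self.phi[:, [1]])


@dataclass
class StimulusDesign:
    """Per-trial laser powers and hologram bookkeeping.

    ``powers`` is the N x K matrix I with I[n, k] the power (mW) on neuron n
    in trial k (0 = untargeted).  Each trial stimulates one hologram (a set of
    target neurons) at a single power drawn from the discrete ``power_set``.
    """

    powers: np.ndarray                  # (N, K) float
    power_set: np.ndarray               # discrete nonzero power levels
    holograms: list                     # list of int arrays (target sets)
    trial_hologram: np.ndarray          # (K,) hologram index per trial
    sweep: np.ndarray                   # (K,) sweep index per trial
    stim_rate: float = 30.0             # Hz

    @property
    def n_neurons(self):
        return self.powers.shape[0]

    @property
    def n_trials(self):
        return self.powers.shape[1]

    def trial_power(self) -> np.ndarray:
        """Scalar laser power of each trial."""
        return self.powers.max(axis=0)


@dataclass
class ExperimentRecord:
    """A simulated (or recorded) mapping experiment.

    ``traces`` holds K raw 45-ms windows (900 samples at 20 kHz, stimulus
    onset at sample 100).  For simulated data, ``target_traces`` holds the
    clean evoked component of each window (the demixing target), and
    ``spikes``/``latencies`` the latent presynaptic activity.
    """

    traces: np.ndarray                       # (K, 900) float
    design: StimulusDesign
    truth: GroundTruth | None = None
    spikes: np.ndarray | None = None         # (N, K) {0,1}
    latencies: np.ndarray | None = None      # (N, K) ms
    mult: np.ndarray | None = None           # (N, K) gain
    target_traces: np.ndarray | None = None  # (K, 900)
    spont_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spont_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    mode: str = "trialwise"
    fs: float = 20000.0
    stim_onset: int = STIM_ONSET
    demixed: np.ndarray | None = None        # (K, 900), filled by nwd.demix
    charges: np.ndarray | None = None        # (K,), filled by nwd

    @property
    def n_trials(self):
        return self.traces.shape[0]


# ---------------------------------------------------------------------------
# ground truth and design sampling


def sample_ground_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw a random circuit: connected set, weights, power curves, kinetics."""
    config.validate()
    n = config.n_neurons
    n_conn = int(np.ceil(config.connect_rate * n))
    connected = np.zeros(n, dtype=bool)
    connected[rng.choice(n, size=n_conn, replace=False)] = True

    # strong minority / weak majority split of the connected population
    conn_idx = np.flatnonzero(connected)
    n_strong = int(round(config.strong_fraction * n_conn))
    strong = np.zeros(n, dtype=bool)
    if n_strong > 0:
        strong[rng.choice(conn_idx, size=n_strong, replace=False)] = True

    weights = np.zeros(n)
    weights[strong] = rng.uniform(config.w_min_strong, config.w_max_strong, size=n_strong)
    weak = connected & ~strong
    weights[weak] = config.w_min_weak + rng.exponential(
        config.w_mean_weak, size=int(weak.sum())
    )

    phi = np.column_stack(
        [
            rng.uniform(*config.phi0_bounds, size=n),
            rng.uniform(*config.phi1_bounds, size=n),
        ]
    )
    tau_r = rng.uniform(*config.tau_r_bounds, size=n)
    tau_d = tau_r + rng.uniform(*config.tau_diff_bounds, size=n)
    return GroundTruth(weights, connected, strong, phi, tau_r, tau_d, config)


def design_stimulus(
    n_neurons: int,
    ensemble_size: int,
    n_sweeps: int,
    power_set=(30.0, 45.0, 60.0),
    stim_rate: float = 30.0,
    fixed_holograms: bool = False,
    n_partitions: int = 3,
    rng: np.random.Generator | None = None,
) -> StimulusDesign:
    """Random ensemble-stimulation design.

    Each sweep randomly partitions all ``n_neurons`` targets into
    ``ceil(N/R)`` holograms of ``ensemble_size`` targets (the last hologram of
    a sweep takes the remainder), so every target is stimulated exactly once
    per sweep.  Trial order and per-trial power (drawn from ``power_set``) are
    randomized.

    With ``fixed_holograms=True`` only ``n_partitions`` distinct partitions
    are drawn and sweeps cycle through them, so every hologram is presented
    repeatedly (across powers) and every neuron appears in ``n_partitions``
    different holograms — the repeated-hologram design needed for
    leave-one-hologram-out validation.  Otherwise a fresh partition is drawn
    each sweep, which maximizes mapping speed.
    """
    rng = np.random.default_rng() if rng is None else rng
    if ensemble_size > n_neurons:
        raise ValueError("ensemble size exceeds population size")
    if ensemble_size < 1:
        raise ValueError("ensemble size must be >= 1")
    power_set = np.asarray(sorted(power_set), dtype=float)

    holograms: list[np.ndarray] = []
    partitions: list[list[int]] = []  # hologram ids per stored partition
    trial_holo = []
    sweep_ix = []
    for s in range(n_sweeps):
        if fixed_holograms and len(partitions) >= n_partitions:
            part_ids = partitions[s % n_partitions]
        else:
            perm = rng.permutation(n_neurons)
            part_ids = []
            for i in range(0, n_neurons, ensemble_size):
                holograms.append(np.sort(perm[i : i + ensemble_size]))
                part_ids.append(len(holograms) - 1)
            if fixed_holograms:
                partitions.append(part_ids)
        for j in rng.permutation(len(part_ids)):
            trial_holo.append(part_ids[j])
            sweep_ix.append(s)

    k = len(trial_holo)
    trial_holo = np.asarray(trial_holo)
    sweep_ix = np.asarray(sweep_ix)
    trial_power = rng.choice(power_set, size=k)
    powers = np.zeros((n_neurons, k))
    for t in range(k):
        powers[holograms[trial_holo[t]], t] = trial_power[t]
    return StimulusDesign(powers, power_set, holograms, trial_holo, sweep_ix, stim_rate)


def expected_revisit_interval(n_neurons: int, ensemble_size: int, stim_rate: float) -> float:
    """Mean time (s) between successive stimulations of a fixed neuron.

    A random R-of-N ensemble contains a given neuron with probability R/N, so
    it is revisited every N/R trials on average, i.e. every N/(R f) seconds.
    """
    if not 1 <= ensemble_size <= n_neurons:
        raise ValueError("require 1 <= R <= N")
    if stim_rate <= 0:
        raise ValueError("stimulation rate must be positive")
    return n_neurons / (ensemble_size * stim_rate)


# ---------------------------------------------------------------------------
# latent activity


def sample_spikes_and_latencies(
    truth: GroundTruth, design: StimulusDesign, rng: np.random.Generator
):
    """Sample the Bernoulli spike matrix s[N, K] and gamma latencies (ms).

    Targeted neurons spike with probability sigmoid(phi0 * I - phi1); spike
    latency is latency_min + Gamma(shape=alpha/I^2, rate=beta), so the mean
    latency decreases with the square of the laser power.
    Latencies are only meaningful where a spike occurred.
    """
    cfg = truth.config
    powers = design.powers
    targeted = powers > 0
    p = sigmoid(truth.phi[:, [0]] * powers - truth.phi[:, [1]])
    spikes = (rng.random(powers.shape) < p) & targeted

    lat = np.full(powers.shape, np.nan)
    if targeted.any():
        shape = cfg.latency_alpha / powers[targeted] ** 2
        lat[targeted] = cfg.latency_min + rng.gamma(shape, 1.0 / cfg.latency_beta)
    return spikes.astype(np.int8), lat


def _sample_spont_kernel(noise: NoiseConfig, rng: np.random.Generator):
    """Random kinetics + charge for one spontaneous PSC.

    Amplitudes mirror the evoked-weight distribution (a strong minority and
    an exponential majority): spontaneous events are real synaptic releases,
    so they span the same range as stimulus-evoked PSCs — which is exactly
    why they can mimic connections.
    """
    tau_r = rng.uniform(0.8, 2.0)
    tau_d = tau_r + rng.uniform(4.0, 10.0)
    if rng.random() < noise.spont_strong_fraction:
        amp = rng.uniform(*noise.spont_strong_range)
    else:
        amp = noise.spont_amp_min + rng.exponential(noise.spont_amp_mean)
    return tau_r, tau_d, amp


def _gp_cholesky(noise: NoiseConfig, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) * DT_MS
    d2 = (t[:, None] - t[None, :]) ** 2
    k = noise.sigma_scale * np.exp(-d2 / (2.0 * noise.ell_gp**2))
    k[np.diag_indices_from(k)] += 1e-8 * noise.sigma_scale
    return np.linalg.cholesky(k)


# ---------------------------------------------------------------------------
# trial-wise simulation


def simulate_trialwise(
    truth: GroundTruth,
    design: StimulusDesign,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> ExperimentRecord:
    """Simulate K independent 45-ms trial windows.

    Each trace is the sum of evoked PSCs (normalized kernels scaled by
    weight x log-normal gain), an optional spontaneous PSC (per-trial
    probability spont_rate * 45 ms, uniform onset), RBF-kernel GP noise and
    i.i.d. Gaussian noise.  The clean evoked component is stored as the
    demixing target.
    """
    noise.validate()
    n, k = design.powers.shape
    spikes, lat = sample_spikes_and_latencies(truth, design, rng)
    mult = np.exp(rng.normal(0.0, truth.config.sigma_mult, size=(n, k)))

    traces = np.zeros((k, TRIAL_SAMPLES))
    target = np.zeros((k, TRIAL_SAMPLES))
    t_grid = np.arange(TRIAL_SAMPLES) * DT_MS
    stim_ms = STIM_ONSET * DT_MS

    conn = np.flatnonzero(truth.connected)
    for nn in conn:
        ks = np.flatnonzero(spikes[nn])
        if ks.size == 0:
            continue
        for kk in ks:
            onset = stim_ms + lat[nn, kk]
            tpl = PSCTemplate(truth.tau_r[nn], truth.tau_d[nn], onset)
            # normalize over full kernel support so in-window charge equals
            # the weight up to the truncated tail
            span = max(TRIAL_SAMPLES, tpl.support_samples())
            wave = tpl.evaluate(span)[:TRIAL_SAMPLES]
            target[kk] += truth.weights[nn] * mult[nn, kk] * spikes[nn, kk] * wave

    traces += target

    # spontaneous PSCs: at most one per window, probability rate * 45 ms
    p_spont = min(1.0, noise.spont_rate * (TRIAL_SAMPLES * DT_MS * 1e-3))
    spont_trials = np.flatnonzero(rng.random(k) < p_spont)
    s_times, s_amps = [], []
    for kk in spont_trials:
        onset = rng.uniform(0.0, t_grid[-1])
        tau_r, tau_d, amp = _sample_spont_kernel(noise, rng)
        tpl = PSCTemplate(tau_r, tau_d, onset)
        span = max(TRIAL_SAMPLES, tpl.support_samples())
        traces[kk] += amp * tpl.evaluate(span)[:TRIAL_SAMPLES]
        s_times.append(kk * TRIAL_SAMPLES * DT_MS + onset)
        s_amps.append(amp)

    if noise.sigma_scale > 0:
        chol = _gp_cholesky(noise, TRIAL_SAMPLES)
        traces += (chol @ rng.standard_normal((TRIAL_SAMPLES, k))).T
    if noise.sigma_noise > 0:
        traces += rng.normal(0.0, noise.sigma_noise, size=traces.shape)

    return ExperimentRecord(
        traces=traces,
        design=design,
        truth=truth,
        spikes=spikes,
        latencies=lat,
        mult=mult,
        target_traces=target,
        spont_times=np.asarray(s_times),
        spont_amps=np.asarray(s_amps),
        mode="trialwise",
    )


# ---------------------------------------------------------------------------
# continuous simulation


def simulate_continuous(
    truth: GroundTruth,
    design: StimulusDesign,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> ExperimentRecord:
    """Simulate one continuous 20-kHz recording and re-window it.

    Trials begin every fs/f samples.  Evoked and spontaneous PSC kernels are
    placed on the long trace at their (integer-rounded-up) onset bins; noise
    follows an AR(1) process.  Windows of 900 samples starting 100 samples
    before each stimulus are then extracted; at stimulation rates above
    ~22 Hz, adjacent windows share samples and PSCs from neighbouring trials
    contaminate each window, which is exactly the confound the demixing
    network is trained to remove.
    """
    noise.validate()
    n, k = design.powers.shape
    if k < 1:
        raise ValueError("design contains no trials")
    step = design.stim_rate and int(round(20000.0 / design.stim_rate))
    if step is None or step <= 0:
        raise ValueError("stimulation rate too high for one trial")

    spikes, lat = sample_spikes_and_latencies(truth, design, rng)
    mult = np.exp(rng.normal(0.0, truth.config.sigma_mult, size=(n, k)))

    max_kernel = int(np.ceil(12.0 * truth.tau_d.max() / DT_MS)) + 1
    total = STIM_ONSET + (k - 1) * step + (TRIAL_SAMPLES - STIM_ONSET) + max_kernel
    c = np.zeros(total)
    trial_starts = STIM_ONSET + step * np.arange(k)

    # evoked events: kernel of neuron n scaled by w * m, onset ceil(t_k + lat)
    kernel_cache: dict[int, np.ndarray] = {}
    for nn in np.flatnonzero(truth.connected):
        ks = np.flatnonzero(spikes[nn])
        if ks.size == 0:
            continue
        if nn not in kernel_cache:
            tpl = PSCTemplate(truth.tau_r[nn], truth.tau_d[nn], 0.0)
            kernel_cache[nn] = tpl.evaluate(tpl.support_samples())
        kern = kernel_cache[nn]
        for kk in ks:
            idx = int(np.ceil(trial_starts[kk] + lat[nn, kk] / DT_MS))
            seg = kern[: total - idx]
            c[idx : idx + seg.size] += truth.weights[nn] * mult[nn, kk] * seg

    # spontaneous events: Poisson train over the whole recording
    duration_s = total * DT_MS * 1e-3
    n_spont = rng.poisson(noise.spont_rate * duration_s)
    s_times = np.sort(rng.uniform(0.0, total * DT_MS, size=n_spont))
    s_amps = np.empty(n_spont)
    for j, t0 in enumerate(s_times):
        tau_r, tau_d, amp = _sample_spont_kernel(noise, rng)
        tpl = PSCTemplate(tau_r, tau_d, 0.0)
        kern = tpl.evaluate(tpl.support_samples())
        idx = int(np.ceil(t0 / DT_MS))
        seg = kern[: total - idx]
        c[idx : idx + seg.size] += amp * seg
        s_amps[j] = amp

    # AR(1) electrode noise; innovation scaled for the target stationary sd
    if noise.sigma_noise > 0:
        innov_sd = noise.sigma_noise * np.sqrt(1.0 - noise.gamma_ar**2)
        eps = lfilter([1.0], [1.0, -noise.gamma_ar], rng.normal(0, innov_sd, size=total))
        c = c + eps

    # window extraction and per-trial clean target component
    traces = np.zeros((k, TRIAL_SAMPLES))
    target = np.zeros((k, TRIAL_SAMPLES))
    for kk in range(k):
        lo = trial_starts[kk] - STIM_ONSET
        traces[kk] = c[lo : lo + TRIAL_SAMPLES]
    for nn in np.flatnonzero(truth.connected):
        kern = kernel_cache.get(nn)
        if kern is None:
            continue
        for kk in np.flatnonzero(spikes[nn]):
            off = STIM_ONSET + int(np.ceil(trial_starts[kk] + lat[nn, kk] / DT_MS)) - trial_starts[kk]
            seg = kern[: TRIAL_SAMPLES - off]
            target[kk, off : off + seg.size] += truth.weights[nn] * mult[nn, kk] * seg

    return ExperimentRecord(
        traces=traces,
        design=design,
        truth=truth,
        spikes=spikes,
        latencies=lat,
        mult=mult,
        target_traces=target,
        spont_times=s_times,
        spont_amps=s_amps,
        mode="continuous",
    )
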