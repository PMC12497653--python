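"""Synthetic training data for the demixing network.

Each training example is a 45-ms trace assembled from three independent PSC
components — currents from the previous trial(s), the target trial, and the
next trial(s) — plus Gaussian-process (RBF kernel) noise and i.i.d. noise
whose variance is itself random.  The regression target is the clean target
component alone: PSCs whose onsets fall inside the admissible initiation
window after the stimulus.  A configurable fraction of examples are pure
noise with an all-zero target, teaching the network to zero out traces with
no evoked current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..kernels import DT_MS, STIM_ONSET, TRIAL_SAMPLES, PSCTemplate
from .network import NWDConfig

#: PSC kinetics presets: (tau_r bounds, tau_diff bounds), ms
KINETICS_PRESETS = {
    "inhibitory": ((0.8, 2.0), (4.0, 10.0)),
    "excitatory": ((0.3, 1.0), (2.0, 6.0)),
}


@dataclass
class NWDTrainingSet:
    inputs: np.ndarray      # (n, 900) noisy mixed traces
    targets: np.ndarray     # (n, 900) clean target-trial component
    is_negative: np.ndarray  # (n,) bool, pure-noise examples
    counts: np.ndarray = None  # (n, 3) PSC counts (prev, target, next)


def _sample_pscs(n_pscs, onset_lo, onset_hi, cfg: NWDConfig, rng) -> np.ndarray:
    """Sum of ``n_pscs`` random templates with onsets in [onset_lo, onset_hi] ms
    relative to window start (negative onsets contribute only their tails)."""
    tau_r_b, tau_diff_b = KINETICS_PRESETS[cfg.kinetics]
    trace = np.zeros(TRIAL_SAMPLES)
    lo, hi = np.log(cfg.amp_range[0]), np.log(cfg.amp_range[1])
    for _ in range(n_pscs):
        tau_r = rng.uniform(*tau_r_b)
        tau_d = tau_r + rng.uniform(*tau_diff_b)
        onset = rng.uniform(onset_lo, onset_hi)
        amp = np.exp(rng.uniform(lo, hi))
        tpl = PSCTemplate(tau_r, tau_d, max(onset, 0.0))
        span = max(TRIAL_SAMPLES, tpl.support_samples())
        wave = tpl.evaluate(span)
        if onset < 0:
            shift = int(round(-onset / DT_MS))
            wave = wave[shift : shift + TRIAL_SAMPLES]
            wave = np.pad(wave, (0, TRIAL_SAMPLES - wave.size))
        else:
            wave = wave[:TRIAL_SAMPLES]
        trace += amp * wave
    return trace


def make_training_set(
    cfg: NWDConfig, n_examples: int, rng: np.random.Generator
) -> NWDTrainingSet:
    """Generate ``n_examples`` (input, target) pairs for NWD training."""
    probs = np.asarray(cfg.psc_count_probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("psc_count_probs must be a distribution over counts")
    probs = probs / probs.sum()
    win_lo, win_hi = cfg.initiation_window_ms
    if not 0 <= win_lo < win_hi:
        raise ValueError("invalid initiation window")
    stim_ms = STIM_ONSET * DT_MS
    t_lo, t_hi = stim_ms + win_lo, stim_ms + win_hi
    window_ms = TRIAL_SAMPLES * DT_MS

    # one Cholesky factor reused for all GP noise draws
    tgrid = np.arange(TRIAL_SAMPLES) * DT_MS
    if cfg.gp_sigma_scale > 0:
        k = cfg.gp_sigma_scale * np.exp(
            -((tgrid[:, None] - tgrid[None, :]) ** 2) / (2 * cfg.gp_lengthscale_ms**2)
        )
        k[np.diag_indices_from(k)] += 1e-8 * cfg.gp_sigma_scale
        chol = np.linalg.cholesky(k)
    else:
        chol = None

    inputs = np.empty((n_examples, TRIAL_SAMPLES))
    targets = np.zeros((n_examples, TRIAL_SAMPLES))
    negative = rng.random(n_examples) < cfg.negative_fraction
    counts = rng.choice(probs.size, size=(n_examples, 3), p=probs)
    for i in range(n_examples):
        if negative[i]:
            signal = np.zeros(TRIAL_SAMPLES)
        else:
            j_prev, j_tar, j_next = counts[i]
            prev = _sample_pscs(j_prev, -window_ms, stim_ms - 3.0, cfg, rng)
            tar = _sample_pscs(j_tar, t_lo, t_hi, cfg, rng)
            nxt = _sample_pscs(j_next, t_hi, window_ms, cfg, rng)
            targets[i] = tar
            signal = prev + tar + nxt
        noise = np.zeros(TRIAL_SAMPLES)
        if chol is not None:
            noise += chol @ rng.standard_normal(TRIAL_SAMPLES)
        var = rng.uniform(*cfg.noise_var_range)
        noise += rng.normal(0.0, np.sqrt(var), size=TRIAL_SAMPLES)
        inputs[i] = signal + noise
    return NWDTrainingSet(inputs, targets, negative, counts)
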