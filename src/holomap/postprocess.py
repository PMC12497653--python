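"""Post-inference analysis: false-negative rescue, canonical waveform
recovery, connectivity-map comparison metrics and leave-one-hologram-out
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import r2_score

from . import caviar
from .caviar import CaviarResult, ModelHyperparams, VariationalState
from .simulate import StimulusDesign, sigmoid


# ---------------------------------------------------------------------------
# map comparison


@dataclass
class MapComparison:
    r2: float
    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    agreement: np.ndarray  # (N,) per-neuron table: 1 TP, 2 FP, 3 FN, 0 TN


def compare_maps(w_ref: np.ndarray, w_est: np.ndarray) -> MapComparison:
    """Compare two connectivity vectors (zeros = unconnected).

    R^2 (coefficient of determination) is computed over the full vectors
    including zeros; precision and recall compare the binarized connectivity
    with ``w_ref`` as ground truth (nonzero weight <=> connected).
    """
    w_ref = np.asarray(w_ref, dtype=float)
    w_est = np.asarray(w_est, dtype=float)
    if w_ref.shape != w_est.shape:
        raise ValueError("weight vectors must have equal length")
    ref_c = w_ref != 0
    est_c = w_est != 0
    tp = int(np.sum(ref_c & est_c))
    fp = int(np.sum(~ref_c & est_c))
    fn = int(np.sum(ref_c & ~est_c))
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if ref_c.any() else np.nan
    agreement = np.zeros(w_ref.size, dtype=int)
    agreement[ref_c & est_c] = 1
    agreement[~ref_c & est_c] = 2
    agreement[ref_c & ~est_c] = 3
    return MapComparison(
        float(r2_score(w_ref, w_est)), precision, recall, tp, fp, fn, agreement
    )


# ---------------------------------------------------------------------------
# canonical waveforms


def estimate_waveforms(
    traces: np.ndarray,
    lam: np.ndarray,
    gamma_ridge: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> np.ndarray:
    """Non-negative ridge recovery of per-neuron canonical PSC waveforms.

    Solves ``argmin_{R >= 0} ||C - Lambda^T R||_F^2 + gamma ||R||_F^2`` by
    accelerated projected gradient, where C is the K x T trace matrix and
    Lambda the N x K inferred spike matrix.  Using inferred spikes rather
    than the stimulation design matrix avoids diluting the waveforms with
    trials on which a targeted neuron never spiked.  Row n integrates
    (times dt) to that neuron's synaptic charge estimate.
    """
    c = np.asarray(traces, dtype=float)
    lam = np.asarray(lam, dtype=float)
    n, k = lam.shape
    if c.shape[0] != k:
        raise ValueError("traces and spike matrix disagree on trial count")
    gram = lam @ lam.T
    lip = 2.0 * (np.linalg.eigvalsh(gram)[-1] + gamma_ridge)
    lc = lam @ c
    r = np.zeros((n, c.shape[1]))
    r_prev = r.copy()
    t_acc = 1.0
    for _ in range(max_iter):
        # FISTA momentum
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        v = r + ((t_acc - 1.0) / t_next) * (r - r_prev)
        grad = 2.0 * (gram @ v - lc) + 2.0 * gamma_ridge * v
        r_new = np.maximum(v - grad / lip, 0.0)
        change = np.linalg.norm(r_new - r) / max(1.0, np.linalg.norm(r))
        r_prev, r, t_acc = r, r_new, t_next
        if change < tol:
            break
    return r


def waveform_objective(traces, lam, r, gamma_ridge):
    """Ridge objective value for a candidate waveform matrix (sanity checks)."""
    fit = np.linalg.norm(traces - lam.T @ r) ** 2
    return fit + gamma_ridge * np.linalg.norm(r) ** 2


# ---------------------------------------------------------------------------
# post hoc false-negative rescue


def false_negative_scan(
    result: CaviarResult,
    y: np.ndarray,
    design: StimulusDesign,
    hyper: ModelHyperparams,
) -> CaviarResult:
    """Greedy rescue of neurons the main pass declared disconnected.

    Repeatedly selects the disconnected neuron with the most coincident
    spontaneous events (trials where it was stimulated and z_k > 0), treats
    those events as putative spikes, and reconnects the neuron if the
    PAVA-fitted coincidence rate at maximum power clears the plausibility
    threshold.  A reconnected neuron's posterior is summarized by the sample
    statistics of the coincident spontaneous charges, its consumed events
    are removed from z, and it is struck from the scan list either way.
    Never disconnects a previously connected neuron; terminates after at
    most |S_disc| rounds.
    """
    state = result.state
    s_disc = set(np.flatnonzero(state.disconnected))
    while s_disc:
        counts = {
            n: int(np.sum((design.powers[n] > 0) & (state.z > 0))) for n in s_disc
        }
        n_star = max(counts, key=lambda n: (counts[n], -n))
        s_disc.discard(n_star)
        if counts[n_star] == 0:
            continue
        coincident = (design.powers[n_star] > 0) & (state.z > 0)
        candidate_spikes = coincident.astype(float)
        curve = caviar.isotonic_power_curve(
            candidate_spikes, design.powers[n_star], design.power_set, state.mask
        )
        if not caviar.plausibility_check(curve, hyper, state.lam_spont):
            continue
        charges = state.z[coincident]
        state.disconnected[n_star] = False
        state.mu[n_star] = float(charges.mean())
        state.Omega[n_star, n_star] = float(charges.var(ddof=0) / charges.size)
        state.lam[n_star] = candidate_spikes
        state.z[coincident] = 0.0
        result.curves[n_star] = curve
    return result


# ---------------------------------------------------------------------------
# leave-one-hologram-out cross-validation


@dataclass
class LOHOResult:
    hologram: np.ndarray        # cell -> hologram id
    power: np.ndarray           # cell -> power level
    observed: np.ndarray        # held-out mean response
    predicted: np.ndarray       # posterior predictive mean
    n_samples: int
    pooled_r2: float
    per_power_r2: dict = field(default_factory=dict)


def posterior_predictive_mean(
    state: VariationalState,
    targets: np.ndarray,
    power: float,
    rng: np.random.Generator,
    n_samples: int = 500,
) -> float:
    """Mean response to stimulating ``targets`` at ``power``, averaging over
    posterior weight, sigmoid-coefficient and spike uncertainty, plus the
    expected spontaneous contribution."""
    idx = np.asarray(targets)
    mu = state.mu[idx]
    cov = state.Omega[np.ix_(idx, idx)]
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(idx.size))
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    w = mu[None, :] + rng.standard_normal((n_samples, idx.size)) @ chol.T
    sd = np.sqrt(np.maximum(state.Sigma[idx][:, [0, 1], [0, 1]], 1e-12))
    phi0 = caviar.sample_truncnorm_pos(
        np.broadcast_to(state.nu[idx, 0], (n_samples, idx.size)),
        np.broadcast_to(sd[:, 0], (n_samples, idx.size)),
        (n_samples, idx.size),
        rng,
    )
    phi1 = caviar.sample_truncnorm_pos(
        np.broadcast_to(state.nu[idx, 1], (n_samples, idx.size)),
        np.broadcast_to(sd[:, 1], (n_samples, idx.size)),
        (n_samples, idx.size),
        rng,
    )
    p_spike = sigmoid(phi0 * power - phi1)
    # disconnected neurons carry zero weight, so their spikes contribute 0
    spikes = rng.random((n_samples, idx.size)) < p_spike
    evoked = (w * spikes).sum(axis=1).mean()
    z_pos = state.z[state.z > 0]
    spont = state.lam_spont * float(z_pos.mean()) if z_pos.size else 0.0
    return float(evoked + spont)


def loho_cv(
    y: np.ndarray,
    design: StimulusDesign,
    hyper: ModelHyperparams | None = None,
    rng: np.random.Generator | None = None,
    traces: np.ndarray | None = None,
    n_samples: int = 500,
    fit_kwargs: dict | None = None,
) -> LOHOResult:
    """Leave-one-hologram-out cross-validation of CAVIaR.

    For each hologram h, CAVIaR is fit on the trials of all other holograms
    and the mean response to h at each power level is predicted from the
    posterior; predictions are compared to held-out observed means.  Requires
    a design with repeated holograms (``fixed_holograms=True``).
    """
    hyper = ModelHyperparams() if hyper is None else hyper
    rng = np.random.default_rng() if rng is None else rng
    fit_kwargs = fit_kwargs or {}
    holo_ids = np.unique(design.trial_hologram)
    # a fresh generator per hologram keyed by its id makes the predictions
    # invariant to the order in which holograms are held out
    root = int(rng.integers(2**31))
    cells = []
    for h in holo_ids:
        rng_h = np.random.default_rng([root, int(h)])
        held = design.trial_hologram == h
        if held.sum() == 0 or (~held).sum() == 0:
            continue
        sub_design = StimulusDesign(
            design.powers[:, ~held],
            design.power_set,
            design.holograms,
            design.trial_hologram[~held],
            design.sweep[~held],
            design.stim_rate,
        )
        sub_traces = traces[~held] if traces is not None else None
        res = caviar.fit(
            y[~held], sub_design, hyper, rng_h, traces=sub_traces, **fit_kwargs
        )
        targets = design.holograms[h]
        for p in np.sort(design.power_set):
            sel = held & (design.powers.max(axis=0) == p)
            if sel.sum() == 0:
                warnings.warn(f"hologram {h} has no held-out trials at power {p}")
                continue
            pred = posterior_predictive_mean(res.state, targets, p, rng_h, n_samples)
            cells.append((h, p, float(y[sel].mean()), pred))
    if not cells:
        raise ValueError("design has no repeated holograms usable for LOHO-CV")
    holo = np.array([c[0] for c in cells])
    power = np.array([c[1] for c in cells])
    obs = np.array([c[2] for c in cells])
    pred = np.array([c[3] for c in cells])
    pooled = float(r2_score(obs, pred))
    per_power = {}
    for p in np.unique(power):
        sel = power == p
        if sel.sum() >= 2:
            per_power[float(p)] = float(r2_score(obs[sel], pred[sel]))
    return LOHOResult(holo, power, obs, pred, n_samples, pooled, per_power)
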