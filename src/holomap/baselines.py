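"""Comparison methods: generic compressed sensing (CoSaMP) and a
spike-and-slab variational ablation without isotonic or spontaneous-current
machinery (CAVI-SnS style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import caviar
from .simulate import StimulusDesign


@dataclass
class BaselineResult:
    weights: np.ndarray
    method: str
    n_iter: int
    sparsity: int | None = None
    extra: dict = field(default_factory=dict)


def cosamp(
    y: np.ndarray,
    design_matrix: np.ndarray,
    sparsity: int,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> BaselineResult:
    """Compressive sampling matching pursuit on the raw stimulation matrix.

    Solves y ~ A^T w for an s-sparse w, where A is the N x K binary
    stimulated/not-stimulated matrix.  No spike model: trials on which a
    targeted neuron failed to spike are averaged in, which biases weight
    estimates toward zero under stochastic spiking.
    """
    a = np.asarray(design_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = a.shape
    if sparsity > n:
        raise ValueError("sparsity exceeds candidate pool size")
    if sparsity <= 0:
        return BaselineResult(np.zeros(n), "cosamp", 0, sparsity)

    w = np.zeros(n)
    resid = y.copy()
    prev_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        proxy = a @ resid
        candidates = np.argsort(np.abs(proxy))[::-1][: 2 * sparsity]
        support = np.union1d(candidates, np.flatnonzero(w))
        sol, *_ = np.linalg.lstsq(a[support].T, y, rcond=None)
        w_full = np.zeros(n)
        w_full[support] = sol
        keep = np.argsort(np.abs(w_full))[::-1][:sparsity]
        w = np.zeros(n)
        w[keep] = w_full[keep]
        # re-solve least squares on the pruned support
        sol, *_ = np.linalg.lstsq(a[keep].T, y, rcond=None)
        w[keep] = sol
        resid = y - a.T @ w
        norm = float(np.linalg.norm(resid))
        if abs(prev_norm - norm) <= tol * max(1.0, np.linalg.norm(y)):
            break
        prev_norm = norm
    return BaselineResult(w, "cosamp", it, sparsity)


def cavi_sns(
    y: np.ndarray,
    design: StimulusDesign,
    hyper: caviar.ModelHyperparams | None = None,
    rng: np.random.Generator | None = None,
    z_score: float = 2.0,
) -> BaselineResult:
    """Spike-and-slab-style variational baseline.

    Runs the CAVIaR engine with the isotonic plausibility rule, trial
    masking and spontaneous-current estimation all disabled (z == 0
    throughout).  Connectivity is decided post hoc by a posterior
    signal-to-noise threshold on the weights (mu_n > z_score * posterior sd)
    instead of the hard disconnect rule.  This approximates earlier
    spike-and-slab variational mapping methods rather than reimplementing
    any one of them line by line.
    """
    hyper = caviar.ModelHyperparams() if hyper is None else hyper
    rng = np.random.default_rng() if rng is None else rng
    res = caviar.fit(
        y, design, hyper, rng, traces=None,
        plausibility=False, spont=False, masking=False,
    )
    mu = res.state.mu.copy()
    sd = np.sqrt(np.clip(np.diag(res.state.Omega), 0.0, None))
    # posterior signal-to-noise gate plus the observation-noise floor (a
    # weight below the per-trial noise sd is indistinguishable from noise)
    sigma = float(np.sqrt(res.state.theta_ra / res.state.theta_sh))
    connected = (mu > z_score * sd) & (mu > sigma)
    w = np.where(connected, mu, 0.0)
    return BaselineResult(
        w, "cavi-sns", res.n_iter,
        extra={"state": res.state, "connected": connected},
    )
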