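"""Demixing inference: forward pass, monotone-decay correction, charge
integration."""

from __future__ import annotations

import numpy as np

from ..kernels import DT_MS, TRIAL_SAMPLES
from .network import UNet1D


def monotone_correct(trace: np.ndarray, t_monotone: int) -> np.ndarray:
    """Force the trace to decay monotonically after sample ``t_monotone``.

    Implements the recursion N_t = min(N_t, N_{t-1}) for all t > t_monotone.
    Idempotent, and never increases any sample.
    """
    out = np.array(trace, dtype=float, copy=True)
    tail = out[..., t_monotone:]
    out[..., t_monotone:] = np.minimum.accumulate(tail, axis=-1)
    return out


def demix(
    model: UNet1D, traces: np.ndarray, t_monotone: int | None = None
) -> np.ndarray:
    """Demix raw trial windows: normalize, network forward pass, undo the
    normalization, then apply the monotone-decay correction."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] != TRIAL_SAMPLES:
        raise ValueError(f"traces must have {TRIAL_SAMPLES} samples")
    t_monotone = model.cfg.t_monotone if t_monotone is None else t_monotone
    out = model.predict(traces)
    return monotone_correct(out, t_monotone)


def integrate_charge(traces: np.ndarray, dt: float = DT_MS) -> np.ndarray:
    """Total charge transfer (pA*ms): sum of the trace times the sample
    interval, over the full window."""
    traces = np.asarray(traces, dtype=float)
    return traces.sum(axis=-1) * dt
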