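"""Postsynaptic-current (PSC) template waveforms.

A PSC transient is modelled as a difference of exponentials with rise time
``tau_r``, decay time ``tau_d`` and onset ``delta`` (all in milliseconds)::

    h~(t) = [exp(-(t - delta)/tau_d) - exp(-(t - delta)/tau_r)] * 1[t >= delta]

The normalized form divides by the discrete-time integral so that the
waveform integrates to one; scaling it by a synaptic weight ``w`` (charge
transfer in pA*ms) then yields a transient whose total charge is ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: sampling interval at 20 kHz, in ms
DT_MS = 0.05
#: samples per 45-ms trial window
TRIAL_SAMPLES = 900
#: sample index of stimulus onset within a trial window (5 ms of context)
STIM_ONSET = 100


class InvalidKineticsError(ValueError):
    """Raised when decay is not slower than rise (tau_d <= tau_r)."""


def psc_shape(t: np.ndarray, tau_r: float, tau_d: float, delta: float = 0.0) -> np.ndarray:
    """Unnormalized difference-of-exponentials transient evaluated at times ``t`` (ms)."""
    if tau_d <= tau_r or tau_r <= 0:
        raise InvalidKineticsError(f"require tau_d > tau_r > 0, got tau_r={tau_r}, tau_d={tau_d}")
    t = np.asarray(t, dtype=float)
    rel = t - delta
    out = np.zeros_like(rel)
    m = rel >= 0
    out[m] = np.exp(-rel[m] / tau_d) - np.exp(-rel[m] / tau_r)
    return out


def psc_peak_time(tau_r: float, tau_d: float, delta: float = 0.0) -> float:
    """Analytic time of the waveform maximum (stationary point of the shape)."""
    return delta + np.log(tau_d / tau_r) / (1.0 / tau_r - 1.0 / tau_d)


@dataclass(frozen=True)
class PSCTemplate:
    """A PSC template with fixed kinetics.

    Parameters
    ----------
    tau_r, tau_d : float
        Rise and decay time constants in ms; ``tau_d > tau_r > 0``.
    delta : float
        Onset time in ms (waveform is zero before it).
    normalized : bool
        If True (default), :meth:`evaluate` rescales the waveform so that its
        discrete-time integral over the evaluation grid equals one.
    """

    tau_r: float
    tau_d: float
    delta: float = 0.0
    normalized: bool = True

    def __post_init__(self):
        if self.tau_d <= self.tau_r or self.tau_r <= 0:
            raise InvalidKineticsError(
                f"require tau_d > tau_r > 0, got tau_r={self.tau_r}, tau_d={self.tau_d}"
            )
        if self.delta < 0:
            raise ValueError("onset delta must be >= 0")

    def evaluate(self, n_samples: int, dt: float = DT_MS) -> np.ndarray:
        """Evaluate the template on a regular grid of ``n_samples`` points.

        With ``normalized=True`` the returned vector ``h`` satisfies
        ``sum(h) * dt == 1`` exactly, so that ``w * h`` carries charge ``w``
        within the grid.
        """
        t = np.arange(n_samples) * dt
        u = psc_shape(t, self.tau_r, self.tau_d, self.delta)
        if not self.normalized:
            return u
        total = u.sum() * dt
        if total <= 0:
            raise ValueError("template has no support on the evaluation grid")
        return u / total

    def support_samples(self, dt: float = DT_MS, tail: float = 12.0) -> int:
        """Number of samples needed to capture the waveform up to ``tail`` decay
        constants past onset (tail mass ~ exp(-tail))."""
        return int(np.ceil((self.delta + tail * self.tau_d) / dt))
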