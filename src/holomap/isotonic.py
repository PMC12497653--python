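"""Weighted least-squares isotonic regression via pool adjacent violators (PAVA).

Used to fit non-decreasing optogenetic power curves (spike probability as a
function of laser power) when judging the biophysical plausibility of
inferred presynaptic spikes.
"""

from __future__ import annotations

import numpy as np


def pava(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Non-decreasing weighted least-squares fit to ``y``.

    Solves min_f sum_i w_i (y_i - f_i)^2 subject to f_1 <= ... <= f_n by
    pooling adjacent violators; the solution is the weighted mean over each
    pooled block.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-D")
    n = y.size
    if n == 0:
        return y.copy()
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match y")

    # blocks as (mean, weight, count) triples merged right-to-left
    means = []
    wts = []
    counts = []
    for i in range(n):
        means.append(y[i])
        wts.append(w[i])
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wts.append(wt)
            counts.append(c1 + c2)
    out = np.empty(n)
    pos = 0
    for m, c in zip(means, counts):
        out[pos : pos + c] = m
        pos += c
    return out
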