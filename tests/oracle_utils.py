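"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the cosine-model oracle
is a direct grid search over (offset, amplitude, phase) refined to 1e-3
resolution, never touching the closed-form least-squares solver.
"""

import numpy as np


def brute_force_cosine_fit(x, y, w, n_rounds=4):
    """Grid-search fit of y ~ a0 + A*cos(2*pi*w*x + phi).

    Coarse-to-fine search: each round lays a 21x21x41 grid over the current
    (a0, A, phi) box and shrinks the box around the best cell, reaching a
    resolution finer than 1e-3 on every parameter.  Returns (a0, A, phi,
    sse).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    span = max(y.max() - y.min(), 1e-6)
    a0_lo, a0_hi = y.min(), y.max()
    A_lo, A_hi = 0.0, span
    p_lo, p_hi = -np.pi, np.pi
    best = None
    for _ in range(n_rounds):
        a0s = np.linspace(a0_lo, a0_hi, 21)
        As = np.linspace(A_lo, A_hi, 21)
        ps = np.linspace(p_lo, p_hi, 41)
        cosv = np.cos(2 * np.pi * w * x[None, :] + ps[:, None])  # (P, n)
        # residuals for all combos: y - a0 - A*cos
        pred = As[:, None, None] * cosv[None, :, :]              # (A, P, n)
        sse = ((y[None, None, None, :] - a0s[:, None, None, None]
                - pred[None, :, :, :]) ** 2).sum(axis=-1)        # (a0, A, P)
        i, j, k = np.unravel_index(np.argmin(sse), sse.shape)
        best = (a0s[i], As[j], ps[k], sse[i, j, k])
        da, dA, dp = a0s[1] - a0s[0], As[1] - As[0], ps[1] - ps[0]
        a0_lo, a0_hi = a0s[i] - da, a0s[i] + da
        A_lo, A_hi = max(As[j] - dA, 0.0), As[j] + dA
        p_lo, p_hi = ps[k] - dp, ps[k] + dp
    return best


def tiled_stride_phase(t, troughs):
    """Per-sample stride phase by explicit enumeration (loop oracle)."""
    out = np.full(np.size(t), np.nan)
    troughs = np.asarray(troughs, float)
    for i, ti in enumerate(np.atleast_1d(t)):
        for s in range(0, troughs.size - 2, 2):
            start, end = troughs[s], troughs[s + 2]
            if start < ti <= end:
                out[i] = 100.0 * (ti - start) / (end - start)
                break
    return out
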