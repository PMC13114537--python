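"""Richardson-extrapolated finite-difference derivatives.

Central second differences at step h have O(h^2) truncation error; combining
evaluations at h and h/2 as (4 D(h/2) - D(h)) / 3 cancels the leading term,
giving O(h^4) accuracy — the same scheme numDeriv-style Hessians use.  Steps
are relative to the magnitude of each coordinate, which matters here because
scale parameters (~1e-4 per squared time unit) and shapes (~1) differ by
orders of magnitude.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hessian", "gradient"]


def _second_diff(f, x, i, j, hi, hj, f0):
    """Central estimate of d2f/dxi dxj at a single step size."""
    x = np.asarray(x, dtype=float)
    if i == j:
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        return (f(xp) - 2.0 * f0 + f(xm)) / hi**2
    out = 0.0
    for si, sj in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
        xx = x.copy()
        xx[i] += si * hi
        xx[j] += sj * hj
        out += (si * sj) * f(xx)
    return out / (4.0 * hi * hj)


def hessian(f, x, rel_step: float = 1e-3, abs_step: float = 1e-6) -> np.ndarray:
    """Richardson-extrapolated Hessian of scalar ``f`` at ``x``.

    Per-coordinate steps ``h_i = rel_step * max(|x_i|, abs_step)``; each
    entry combines the central second difference at ``h`` and ``h/2``.
    """
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * np.maximum(np.abs(x), abs_step)
    f0 = f(x)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            d1 = _second_diff(f, x, i, j, h[i], h[j], f0)
            d2 = _second_diff(f, x, i, j, h[i] / 2, h[j] / 2, f0)
            H[i, j] = H[j, i] = (4.0 * d2 - d1) / 3.0
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite entries in numerical Hessian")
    return H


def gradient(f, x, rel_step: float = 1e-6, abs_step: float = 1e-9) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(np.abs(x), abs_step)
    g = np.empty(len(x))
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (f(xp) - f(xm)) / (2.0 * h[i])
    return g
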