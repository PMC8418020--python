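"""Finite-difference gradients and Hessians with relative step scaling."""

from __future__ import annotations

import numpy as np


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def forward_gradient(f, x, f0=None, rel_step: float = 1e-7) -> np.ndarray:
    """One-sided gradient; cheap (p evaluations), O(h) accurate."""
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = f(x)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += h[i]
        g[i] = (f(xp) - f0) / h[i]
    return g


def central_gradient(f, x, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient; 2p evaluations, O(h^2) accurate."""
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (f(xp) - f(xm)) / (2 * h[i])
    return g


def central_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian (~2p^2 evaluations)."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = _steps(x, rel_step)
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            # O(h^2) cross term using the already-computed axis points
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * h[i] * h[j])
    return H
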