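"""Euler-Maruyama stepping kernels, JIT-compiled when numba is available.

Noise arrays are generated by the caller (one seeded stream per simulation,
consumed in documented order), so trajectories are bitwise identical with or
without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def em_poly(x0, dt, drift_deg, drift_c, diff_deg, diff_c, polar, noise):
    """Generic polynomial-library model; returns (trajectory, fail_index)."""
    n = noise.shape[0]
    out = np.empty(n + 1)
    out[0] = x0
    x = x0
    sqdt = np.sqrt(dt)
    for k in range(n):
        f = 0.0
        for j in range(drift_deg.shape[0]):
            f += drift_c[j] * x ** drift_deg[j]
        s = 0.0
        for j in range(diff_deg.shape[0]):
            s += diff_c[j] * x ** diff_deg[j]
        if polar:
            f += s * s / (2.0 * x)
        x = x + f * dt + s * sqdt * noise[k]
        out[k + 1] = x
        if not np.isfinite(x):
            return out, k
    return out, -1


@njit(cache=True)
def em_colored_pitchfork(x0, eta0, lam, mu, alpha, sigma_eta, dt, noise):
    """Cubic drift forced by an Ornstein-Uhlenbeck latent state (1 draw/step)."""
    n = noise.shape[0]
    out = np.empty(n + 1)
    out[0] = x0
    x = x0
    eta = eta0
    sqdt = np.sqrt(dt)
    for k in range(n):
        x_new = x + (lam * x - mu * x**3 + eta) * dt
        eta = eta - alpha * eta * dt + sigma_eta * sqdt * noise[k]
        x = x_new
        out[k + 1] = x
        if not (np.isfinite(x) and np.isfinite(eta)):
            return out, k
    return out, -1


@njit(cache=True)
def em_double_well(x0, v0, eps, sigma, dt, noise):
    """Second-order particle, damping 2, noise on the velocity (1 draw/step)."""
    n = noise.shape[0]
    out = np.empty(n + 1)
    out[0] = x0
    x = x0
    v = v0
    sqdt = np.sqrt(dt)
    for k in range(n):
        x_new = x + v * dt
        v = v + (eps * x - x**3 - 2.0 * v) * dt + sigma * sqdt * noise[k]
        x = x_new
        out[k + 1] = x
        if not (np.isfinite(x) and np.isfinite(v)):
            return out, k
    return out, -1


@njit(cache=True)
def em_wake_2d(x0, y0, lam, mu, sigma0, sigma1, dt, noise):
    """Symmetric 2D pitchfork with isotropic state-dependent noise.

    noise has shape (n, 2): x-draw then y-draw each step.  Records r.
    """
    n = noise.shape[0]
    out = np.empty(n + 1)
    x = x0
    y = y0
    out[0] = np.sqrt(x * x + y * y)
    sqdt = np.sqrt(dt)
    for k in range(n):
        r2 = x * x + y * y
        g = lam - mu * r2
        s = sigma0 + sigma1 * r2
        x = x + g * x * dt + s * sqdt * noise[k, 0]
        y = y + g * y * dt + s * sqdt * noise[k, 1]
        out[k + 1] = np.sqrt(x * x + y * y)
        if not (np.isfinite(x) and np.isfinite(y)):
            return out, k
    return out, -1
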