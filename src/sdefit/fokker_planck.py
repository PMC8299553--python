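"""Discretized forward/adjoint Fokker-Planck operators on a 1D grid.

The forward operator acts on densities, ``L p = -(f p)' + (a p)''``, built in
conservative (flux) form with zero-flux boundaries so that discrete
probability is conserved exactly.  The adjoint acts on observables,
``L+ g = f g' + a g''``, discretized with second-order central differences in
the interior and second-order one-sided stencils at the two boundary rows.
The two operators are discretized independently, not by transposition.

Finite-time conditional moments are obtained by propagating the observables
x and x**2 through ``expm(tau * L+)``:

    m1(x) = w1(x, tau) - x
    m2(x) = w2(x, tau) - 2 x w1(x, tau) + x**2

The operator grid extends the data grid (default 25% of its span per side,
same spacing) to push boundary artifacts away from the bins entering the
cost; results are restricted back to the data-grid centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import expm

from .models import InfeasibleModelError, LangevinModel
from .moments import Grid1D

__all__ = [
    "NumericalError",
    "SolverError",
    "GridOperators",
    "FiniteTimeMoments",
    "StationaryPDF",
    "build_operators",
    "finite_time_moments",
    "stationary_pdf_analytic",
    "stationary_pdf_numeric",
]


class NumericalError(RuntimeError):
    """Non-finite values produced by operator propagation."""


class SolverError(RuntimeError):
    """Stationary solver failed (degenerate or ill-conditioned null space)."""


@dataclass
class GridOperators:
    grid: Grid1D
    forward: np.ndarray
    adjoint: np.ndarray
    boundary: str = "zero-flux/one-sided"


@dataclass
class FiniteTimeMoments:
    grid: Grid1D
    tau: float
    m1: np.ndarray
    m2: np.ndarray
    w1_field: np.ndarray
    w2_field: np.ndarray


@dataclass
class StationaryPDF:
    grid: Grid1D
    density: np.ndarray
    source: str  # "analytic" | "numeric"


def _drift_diffusion_on(model: LangevinModel, x: np.ndarray):
    sigma = model.sigma(x, check_positive=False)
    if np.any(sigma <= 0):
        raise InfeasibleModelError(
            f"sigma(x) <= 0 on grid (min sigma = {sigma.min():.3g})"
        )
    f = model.drift(x, check_domain=False)
    a = 0.5 * sigma**2
    return f, a


def _adjoint_matrix(f: np.ndarray, a: np.ndarray, h: float) -> np.ndarray:
    n = f.size
    if n < 4:
        raise ValueError("adjoint discretization needs at least 4 grid points")
    A = np.zeros((n, n))
    i = np.arange(1, n - 1)
    A[i, i - 1] = -f[i] / (2 * h) + a[i] / h**2
    A[i, i] = -2 * a[i] / h**2
    A[i, i + 1] = f[i] / (2 * h) + a[i] / h**2
    # second-order one-sided stencils at the boundary rows
    A[0, :4] = f[0] * np.array([-3, 4, -1, 0]) / (2 * h) + a[0] * np.array(
        [2, -5, 4, -1]
    ) / h**2
    A[-1, -4:] = f[-1] * np.array([0, 1, -4, 3]) / (2 * h) + a[-1] * np.array(
        [-1, 4, -5, 2]
    ) / h**2
    return A


def _forward_matrix(f: np.ndarray, a: np.ndarray, h: float) -> np.ndarray:
    """Conservative flux-form discretization with zero-flux boundaries.

    Interface fluxes F_{i+1/2} = f_{i+1/2} (p_i + p_{i+1})/2
                               - (a_{i+1} p_{i+1} - a_i p_i)/h,
    with F = 0 at the outer boundaries; L p_i = -(F_{i+1/2} - F_{i-1/2})/h.
    Column sums vanish exactly (telescoping), so probability is conserved.
    """
    n = f.size
    L = np.zeros((n, n))
    fm = 0.5 * (f[:-1] + f[1:])
    i = np.arange(n - 1)
    c_lo = 0.5 * fm + a[:-1] / h  # coefficient of p_i in F_{i+1/2}
    c_hi = 0.5 * fm - a[1:] / h  # coefficient of p_{i+1} in F_{i+1/2}
    L[i, i] -= c_lo / h
    L[i, i + 1] -= c_hi / h
    L[i + 1, i] += c_lo / h
    L[i + 1, i + 1] += c_hi / h
    return L


def build_operators(model: LangevinModel, grid: Grid1D) -> GridOperators:
    """Forward and adjoint Fokker-Planck matrices on the given grid."""
    x = grid.centers
    f, a = _drift_diffusion_on(model, x)
    return GridOperators(
        grid=grid,
        forward=_forward_matrix(f, a, grid.h),
        adjoint=_adjoint_matrix(f, a, grid.h),
    )


def extend_grid(
    grid: Grid1D, fraction: float = 0.25, positive: bool = False
) -> tuple[Grid1D, slice]:
    """Extend a grid by whole cells on each side; returns (grid, restriction).

    ``positive=True`` clamps the lower extension so no edge crosses zero
    (radial-coordinate models).  The slice maps extended-grid center arrays
    back onto the original centers.
    """
    n = grid.n_bins
    h = grid.h
    k = max(0, math.ceil(fraction * n))
    k_lo = k
    if positive:
        k_lo = min(k, int(math.floor(grid.edges[0] / h + 1e-9)))
        k_lo = max(k_lo, 0)
    lo = grid.edges[0] - k_lo * h
    hi = grid.edges[-1] + k * h
    ext = Grid1D(edges=np.linspace(lo, hi, n + k_lo + k + 1))
    return ext, slice(k_lo, k_lo + n)


def _propagate_cn(A: np.ndarray, W: np.ndarray, tau: float, n_steps: int = 64):
    """Crank-Nicolson time stepping of dW/dt = A W (fallback for large grids)."""
    dt = tau / n_steps
    eye = np.eye(A.shape[0])
    lhs = eye - 0.5 * dt * A
    rhs = eye + 0.5 * dt * A
    step = np.linalg.solve(lhs, rhs)
    for _ in range(n_steps):
        W = step @ W
    return W


def finite_time_moments(
    model: LangevinModel,
    grid: Grid1D,
    tau: float,
    extend_fraction: float = 0.25,
    method: str = "auto",
) -> FiniteTimeMoments:
    """Exact finite-time conditional moments of the model at sampling gap tau.

    Propagates the observables x and x**2 through the adjoint exponential on
    an extended grid, then restricts back to the data-grid centers.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    x_data = grid.centers
    if tau == 0:
        z = np.zeros_like(x_data)
        return FiniteTimeMoments(
            grid=grid, tau=0.0, m1=z.copy(), m2=z.copy(),
            w1_field=x_data.copy(), w2_field=x_data**2,
        )
    ext, sl = extend_grid(grid, extend_fraction, positive=model.polar_ito_term)
    x = ext.centers
    ops = build_operators(model, ext)
    W0 = np.column_stack([x, x**2])
    if method == "auto":
        method = "expm" if x.size <= 400 else "cn"
    if method == "expm":
        W = expm(tau * ops.adjoint) @ W0
    elif method == "cn":
        W = _propagate_cn(ops.adjoint, W0, tau)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(W)):
        raise NumericalError(
            "adjoint propagation produced non-finite values "
            f"(tau={tau}, n={x.size}, h={ext.h:.3g})"
        )
    w1, w2 = W[:, 0], W[:, 1]
    m1 = w1 - x
    m2 = w2 - 2 * x * w1 + x**2
    return FiniteTimeMoments(
        grid=grid, tau=float(tau),
        m1=m1[sl].copy(), m2=m2[sl].copy(),
        w1_field=w1[sl].copy(), w2_field=w2[sl].copy(),
    )


def stationary_pdf_analytic(
    model: LangevinModel, grid: Grid1D
) -> StationaryPDF:
    """Zero-flux stationary density p(x) = C / a(x) * exp(int f/a dx).

    Cumulative quadrature on the grid centers; reduces to the constant-sigma
    closed form ``C exp(2/sigma^2 int f dx)`` when sigma is constant.
    """
    x = grid.centers
    f, a = _drift_diffusion_on(model, x)
    psi = cumulative_trapezoid(f / a, x, initial=0.0)
    logp = psi - np.log(a)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum() * grid.h
    return StationaryPDF(grid=grid, density=p, source="analytic")


def stationary_pdf_numeric(
    model: LangevinModel, grid: Grid1D
) -> StationaryPDF:
    """Null vector of the discrete forward operator, normalized.

    The discrete zero-flux operator has an exact zero eigenvalue; the
    corresponding eigenvector is sign-fixed, tiny negative entries are
    clipped, and the result is normalized on the grid.
    """
    ops = build_operators(model, grid)
    L = ops.forward
    lam, V = np.linalg.eig(L)
    scale = np.abs(lam).max()
    if scale == 0:
        raise SolverError("forward operator is identically zero")
    small = np.abs(lam) < 1e-8 * scale
    if small.sum() != 1:
        raise SolverError(
            f"null space dimension {small.sum()} != 1 "
            f"(|lambda|/max: {np.sort(np.abs(lam))[:3] / scale})"
        )
    v = V[:, int(np.argmin(np.abs(lam)))]
    if np.abs(v.imag).max() > 1e-8 * np.abs(v.real).max():
        raise SolverError("stationary eigenvector is not real")
    p = v.real
    if p.sum() < 0:
        p = -p
    p = p / (p.sum() * grid.h)
    neg = p < 0
    if np.any(p < -1e-8 * p.max()):
        raise SolverError(
            f"stationary density has significant negative entries "
            f"(min {p.min():.3g} vs max {p.max():.3g})"
        )
    p[neg] = 0.0
    p = p / (p.sum() * grid.h)
    return StationaryPDF(grid=grid, density=p, source="numeric")
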