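"""Cost evaluation, coefficient optimization and stepwise sparse selection.

The cost couples two consistency requirements: the model's exact finite-time
conditional moments (adjoint propagation) must match the binned empirical
moments, and the model's stationary density must match the empirical
histogram, weighted by ``eta``:

    J(xi) = sum_n sum_i w_i^(n) [m^(n)(x_i; xi) - mhat^(n)(x_i)]^2
            + eta * D_KL(phat, p(.; xi))

Coefficients are found by restarted Nelder-Mead; model structure by
reverse-greedy stepwise regression that repeatedly removes the term whose
elimination least increases the refitted cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .fokker_planck import (
    NumericalError,
    SolverError,
    StationaryPDF,
    finite_time_moments,
    stationary_pdf_analytic,
    stationary_pdf_numeric,
)
from .models import InfeasibleModelError, LangevinModel
from .moments import (
    BinnedMoments,
    EmpiricalPDF,
    Grid1D,
    SamplingPlan,
    TimeSeries,
    empirical_pdf,
    estimate_moments,
    subsample,
)

__all__ = [
    "FitFailureError",
    "FitConfig",
    "CostBreakdown",
    "FitResult",
    "SSRLevel",
    "SSRPath",
    "moment_cost",
    "kl_divergence",
    "total_cost",
    "choose_eta",
    "nearest_power_of_ten",
    "fit",
    "fit_no_adjoint",
    "ssr",
]

logger = logging.getLogger(__name__)


class FitFailureError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Knobs for the estimation pipeline.  Defaults follow the documented
    conventions: 40 bins over the 0.05-99.95 percentile range, min_count 10,
    inverse-squared-standard-error weights, 25% operator-grid extension."""

    stride: int = 1
    eta: float | str = "auto"
    eta_floor: float = 1e-6
    max_iter: int = 400
    x_tol: float = 1e-6
    f_tol: float = 1e-10
    simplex_scale: float = 0.3
    restarts: int = 3
    seed: int = 0
    infeasibility_penalty: float = 1e10
    n_bins: int = 40
    trim: tuple[float, float] = (0.05, 99.95)
    min_count: int = 10
    uniform_weights: bool = False
    extend_fraction: float = 0.25
    knee_factor: float = 2.0
    stationary_method: str = "numeric"  # "numeric" (analytic fallback) | "analytic"
    track_history: bool = False

    def __post_init__(self):
        if isinstance(self.eta, str):
            if self.eta != "auto":
                raise ValueError(f"eta must be a number or 'auto', got {self.eta!r}")
        elif self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CostBreakdown:
    moment_term: float
    kl_term: float
    eta: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.moment_term + self.eta * self.kl_term


@dataclass
class FitResult:
    model: LangevinModel
    cost: CostBreakdown
    converged: bool
    n_evaluations: int
    history: list | None = None


@dataclass
class SSRLevel:
    active_terms: tuple[str, ...]
    coeffs: np.ndarray  # full-length vector, zeros on inactive terms
    cost: CostBreakdown


@dataclass
class SSRPath:
    structure: LangevinModel
    levels: list[SSRLevel]
    selected_index: int

    def model_at(self, index: int) -> LangevinModel:
        return self.structure.with_coeff_vector(self.levels[index].coeffs)

    @property
    def selected_model(self) -> LangevinModel:
        return self.model_at(self.selected_index)


# ---------------------------------------------------------------------------
# cost pieces
# ---------------------------------------------------------------------------


def moment_cost(
    model: LangevinModel,
    binned: BinnedMoments,
    extend_fraction: float = 0.25,
    infeasibility_penalty: float = 1e10,
) -> float:
    """Weighted squared mismatch between model and empirical moments.

    Infeasible models (sigma <= 0 on the operator grid) return the finite
    penalty instead of raising, keeping simplex searches well defined.
    """
    try:
        ftm = finite_time_moments(
            model, binned.grid, binned.tau, extend_fraction=extend_fraction
        )
    except (InfeasibleModelError, NumericalError):
        return float(infeasibility_penalty)
    v = binned.valid
    r1 = ftm.m1[v] - binned.m1[v]
    r2 = ftm.m2[v] - binned.m2[v]
    cost = float(
        np.sum(binned.weights1[v] * r1**2) + np.sum(binned.weights2[v] * r2**2)
    )
    if not np.isfinite(cost):
        return float(infeasibility_penalty)
    return cost


def kl_divergence(p_hat: EmpiricalPDF, p_model: StationaryPDF) -> float:
    """D_KL(phat, p) = sum_i phat_i log(phat_i / p_i) h, over bins phat_i > 0."""
    if p_hat.grid.n_bins != p_model.grid.n_bins or not np.allclose(
        p_hat.grid.edges, p_model.grid.edges
    ):
        raise ValueError("empirical and model PDFs live on different grids")
    h = p_hat.grid.h
    mask = p_hat.density > 0
    p = np.maximum(p_model.density[mask], 1e-300)
    q = p_hat.density[mask]
    val = float(np.sum(q * np.log(q / p)) * h)
    return max(val, 0.0)


def _model_stationary(
    model: LangevinModel, grid: Grid1D, method: str
) -> StationaryPDF:
    if method == "analytic":
        return stationary_pdf_analytic(model, grid)
    try:
        return stationary_pdf_numeric(model, grid)
    except SolverError:
        return stationary_pdf_analytic(model, grid)


def total_cost(
    model: LangevinModel,
    binned: BinnedMoments,
    p_hat: EmpiricalPDF,
    eta: float,
    extend_fraction: float = 0.25,
    infeasibility_penalty: float = 1e10,
    stationary_method: str = "numeric",
) -> CostBreakdown:
    """Moment cost plus eta-weighted KL regularization."""
    mc = moment_cost(
        model, binned,
        extend_fraction=extend_fraction,
        infeasibility_penalty=infeasibility_penalty,
    )
    if mc >= infeasibility_penalty:
        return CostBreakdown(moment_term=mc, kl_term=0.0, eta=eta)
    if eta == 0:
        return CostBreakdown(moment_term=mc, kl_term=0.0, eta=eta)
    try:
        p_model = _model_stationary(model, p_hat.grid, stationary_method)
        kl = kl_divergence(p_hat, p_model)
    except (InfeasibleModelError, SolverError):
        return CostBreakdown(
            moment_term=float(infeasibility_penalty), kl_term=0.0, eta=eta
        )
    return CostBreakdown(moment_term=mc, kl_term=kl, eta=eta)


def nearest_power_of_ten(c: float, floor: float = 1e-6) -> float:
    """Power of ten nearest to c in log space, floored for degenerate c."""
    if c <= floor:
        return floor
    return float(10.0 ** np.round(np.log10(c)))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _objective_factory(structure, binned, p_hat, eta, config, active):
    n_full = structure.n_params

    def unpack(theta_active):
        full = np.zeros(n_full)
        full[active] = theta_active
        return structure.with_coeff_vector(full)

    def obj(theta_active):
        model = unpack(theta_active)
        cb = total_cost(
            model, binned, p_hat, eta,
            extend_fraction=config.extend_fraction,
            infeasibility_penalty=config.infeasibility_penalty,
            stationary_method=config.stationary_method,
        )
        return cb.total

    return unpack, obj


def _initial_simplex(x0: np.ndarray, scale: float) -> np.ndarray:
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for j in range(n):
        simplex[j + 1, j] += scale * max(abs(x0[j]), 0.5)
    return simplex


def _optimize(structure, binned, p_hat, eta, config, active, starts):
    """Restarted Nelder-Mead over the active coefficients; best of all starts."""
    unpack, obj = _objective_factory(
        structure, binned, p_hat, eta, config, active
    )
    best = None
    n_eval = 0
    history = [] if config.track_history else None
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        res = minimize(
            obj,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter,
                "xatol": config.x_tol,
                "fatol": config.f_tol,
                "initial_simplex": _initial_simplex(x0, config.simplex_scale),
            },
        )
        n_eval += res.nfev
        if history is not None:
            history.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= config.infeasibility_penalty:
        raise FitFailureError("all optimizer restarts ended infeasible")
    model = unpack(best.x)
    cb = total_cost(
        model, binned, p_hat, eta,
        extend_fraction=config.extend_fraction,
        infeasibility_penalty=config.infeasibility_penalty,
        stationary_method=config.stationary_method,
    )
    return FitResult(
        model=model,
        cost=cb,
        converged=bool(best.success),
        n_evaluations=n_eval,
        history=history,
    )


def _no_adjoint_theta(structure, binned, active=None):
    """Weighted linear least squares ignoring the finite-time correction.

    sigma(x) is fitted from sqrt(m2/tau) (so the diffusion parameterization
    stays linear), then the drift from m1/tau minus the structural polar
    contribution.  Returns the full coefficient vector.
    """
    x = binned.grid.centers[binned.valid]
    if x.size == 0:
        raise FitFailureError("no valid bins for the baseline fit")
    tau = binned.tau
    nf = len(structure.drift_library)
    ns = len(structure.diffusion_library)
    if active is None:
        active = np.ones(nf + ns, dtype=bool)
    w1 = binned.weights1[binned.valid]
    w2 = binned.weights2[binned.valid]
    m1 = binned.m1[binned.valid]
    m2 = binned.m2[binned.valid]

    def wls(design, y, w):
        sw = np.sqrt(w)
        A = design * sw[:, None]
        b = y * sw
        if A.size == 0 or np.linalg.matrix_rank(A) < A.shape[1]:
            raise FitFailureError("rank-deficient library on valid bins")
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        return coef

    theta = np.zeros(nf + ns)
    act_s = active[nf:]
    if np.any(act_s):
        sig_hat = np.sqrt(np.maximum(m2, 0.0) / tau)
        design_s = structure.diffusion_library.design_matrix(x)[:, act_s]
        theta_s = wls(design_s, sig_hat, w2)
        theta[nf:][act_s] = theta_s
    act_f = active[:nf]
    if np.any(act_f):
        y = m1 / tau
        if structure.polar_ito_term:
            trial = structure.with_coeff_vector(theta)
            y = y - trial.diffusion_a(x) / x
        design_f = structure.drift_library.design_matrix(x)[:, act_f]
        theta_f = wls(design_f, y, w1)
        theta[:nf][act_f] = theta_f
    return theta


def _no_adjoint_cost(structure, theta, binned):
    """Direct weighted residual of m1/tau and m2/(2 tau) on the libraries."""
    model = structure.with_coeff_vector(theta)
    v = binned.valid
    x = binned.grid.centers[v]
    tau = binned.tau
    f = model.drift(x, check_domain=False)
    a = model.diffusion_a(x)
    r1 = f - binned.m1[v] / tau
    r2 = a - binned.m2[v] / (2 * tau)
    return float(
        np.sum(binned.weights1[v] * r1**2) + np.sum(binned.weights2[v] * r2**2)
    )


def _prepare(ts: TimeSeries, config: FitConfig):
    plan = SamplingPlan(config.stride)
    sub = subsample(ts, plan)
    grid = Grid1D.from_data(sub.values, config.n_bins, config.trim)
    binned = estimate_moments(
        ts, grid, plan,
        min_count=config.min_count,
        uniform_weights=config.uniform_weights,
    )
    p_hat = empirical_pdf(sub, grid)
    return grid, binned, p_hat


def _starts_from_baseline(structure, binned, config, active):
    n_act = int(np.sum(active))
    try:
        theta0 = _no_adjoint_theta(structure, binned, active)[active]
    except FitFailureError:
        theta0 = np.ones(n_act)
    rng = np.random.default_rng(config.seed)
    starts = [theta0, 2.0 * theta0,
              theta0 * (1.0 + 0.5 * rng.standard_normal(n_act))]
    return starts[: max(1, config.restarts)]


def choose_eta(
    structure: LangevinModel,
    binned: BinnedMoments,
    p_hat: EmpiricalPDF,
    config: FitConfig,
) -> float:
    """Power of ten nearest to the minimum cost of an unregularized fit."""
    active = np.ones(structure.n_params, dtype=bool)
    starts = _starts_from_baseline(structure, binned, config, active)
    res = _optimize(structure, binned, p_hat, 0.0, config, active, starts)
    return nearest_power_of_ten(res.cost.total, config.eta_floor)


def fit(
    structure: LangevinModel, ts: TimeSeries, config: FitConfig
) -> FitResult:
    """Full estimation pipeline: subsample, bin, select eta, optimize.

    Deterministic given the config seed.  The returned model carries the
    data-grid extent as its domain.
    """
    if structure.n_params < 1:
        raise ValueError("structure must have at least one free coefficient")
    grid, binned, p_hat = _prepare(ts, config)
    structure = structure.with_domain((grid.edges[0], grid.edges[-1]))
    active = np.ones(structure.n_params, dtype=bool)
    starts = _starts_from_baseline(structure, binned, config, active)
    eta = config.eta
    if eta == "auto":
        eta = choose_eta(structure, binned, p_hat, config)
        logger.info("auto-selected eta = %g", eta)
    return _optimize(structure, binned, p_hat, float(eta), config, active, starts)


def fit_no_adjoint(
    structure: LangevinModel, ts: TimeSeries, config: FitConfig
) -> FitResult:
    """Baseline without the finite-time correction.

    Weighted linear least squares of m1/tau on the drift library and of the
    diffusion amplitude on the diffusion library.  The reported cost is the
    direct (uncorrected) weighted residual with no KL term.
    """
    grid, binned, p_hat = _prepare(ts, config)
    structure = structure.with_domain((grid.edges[0], grid.edges[-1]))
    theta = _no_adjoint_theta(structure, binned)
    model = structure.with_coeff_vector(theta)
    cb = CostBreakdown(
        moment_term=_no_adjoint_cost(structure, theta, binned),
        kl_term=0.0,
        eta=0.0,
    )
    return FitResult(model=model, cost=cb, converged=True, n_evaluations=0)


# ---------------------------------------------------------------------------
# stepwise sparse regression
# ---------------------------------------------------------------------------


def _fit_subset(structure, binned, p_hat, eta, config, active, parent_theta):
    """Refit with only the active coefficients free; warm + baseline starts."""
    starts = [parent_theta[active]]
    try:
        starts.append(_no_adjoint_theta(structure, binned, active)[active])
    except FitFailureError:
        pass
    return _optimize(structure, binned, p_hat, eta, config, active, starts)


def ssr(
    drift_lib,
    diff_lib,
    ts: TimeSeries,
    config: FitConfig,
    polar_ito_term: bool = False,
) -> SSRPath:
    """Reverse-greedy stepwise sparse regression over both libraries.

    Starting from the full model, each level refits every one-term-smaller
    candidate and permanently removes the term whose removal yields the
    smallest refitted cost (ties broken toward removing the higher-degree
    term).  eta is fixed across the path for comparability.  The selected
    level is the smallest model whose cost is within ``knee_factor`` of the
    path minimum; the full path is always reported.
    """
    nf, ns = len(drift_lib), len(diff_lib)
    if nf + ns < 2:
        raise ValueError("combined library must have at least 2 terms")
    structure = LangevinModel(
        drift_library=drift_lib,
        drift_coeffs=np.zeros(nf),
        diffusion_library=diff_lib,
        diffusion_coeffs=np.zeros(ns),
        polar_ito_term=polar_ito_term,
    )
    grid, binned, p_hat = _prepare(ts, config)
    structure = structure.with_domain((grid.edges[0], grid.edges[-1]))
    labels = structure.term_labels
    degrees = np.array(
        structure.drift_library.degrees + structure.diffusion_library.degrees
    )

    eta = config.eta
    if eta == "auto":
        eta = choose_eta(structure, binned, p_hat, config)
        logger.info("ssr: auto-selected eta = %g", eta)
    eta = float(eta)

    active = np.ones(nf + ns, dtype=bool)
    full_starts = _starts_from_baseline(structure, binned, config, active)
    res = _optimize(structure, binned, p_hat, eta, config, active, full_starts)
    def _active_labels(mask):
        return tuple(l for l, a in zip(labels, mask) if a)

    theta = res.model.coeff_vector()
    levels = [
        SSRLevel(
            active_terms=_active_labels(active),
            coeffs=theta.copy(),
            cost=res.cost,
        )
    ]

    while int(active.sum()) > 1:
        candidates = []  # (cost_total, -degree, idx, result)
        for idx in np.nonzero(active)[0]:
            trial = active.copy()
            trial[idx] = False
            if not np.any(trial[nf:]):
                # removing the last diffusion term makes sigma == 0 everywhere
                candidates.append((np.inf, -degrees[idx], idx, None))
                continue
            try:
                r = _fit_subset(
                    structure, binned, p_hat, eta, config, trial, theta
                )
                candidates.append((r.cost.total, -degrees[idx], idx, r))
            except FitFailureError:
                candidates.append((np.inf, -degrees[idx], idx, None))
        candidates.sort(key=lambda c: (c[0], c[1]))
        cost_total, _, idx, r = candidates[0]
        if r is None:
            raise FitFailureError(
                "every candidate removal was infeasible; path cannot continue"
            )
        active[idx] = False
        theta = r.model.coeff_vector()
        levels.append(
            SSRLevel(
                active_terms=_active_labels(active),
                coeffs=theta.copy(),
                cost=r.cost,
            )
        )

    totals = np.array([lv.cost.total for lv in levels])
    min_total = totals.min()
    selected = 0
    for i in range(len(levels) - 1, -1, -1):
        if totals[i] <= config.knee_factor * min_total:
            selected = i
            break
    return SSRPath(structure=structure, levels=levels, selected_index=selected)
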