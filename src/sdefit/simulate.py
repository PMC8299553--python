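"""Synthetic trajectory generators and validation statistics.

All generators use the Euler-Maruyama scheme with a single seeded
pseudo-random stream per simulation; for two-variable systems the stream is
consumed in a fixed documented order so runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import _kernels
from .models import LangevinModel
from .moments import TimeSeries

__all__ = [
    "SimulationError",
    "SimSpec",
    "ColoredPitchforkParams",
    "DoubleWellParams",
    "WakeSurrogateParams",
    "euler_maruyama",
    "simulate_colored_pitchfork",
    "simulate_double_well",
    "simulate_wake_surrogate",
    "dwell_times",
    "power_spectrum",
]


class SimulationError(RuntimeError):
    """Trajectory blow-up; reports the offending step index."""


@dataclass
class SimSpec:
    """Integration settings.  burn_in defaults to 1% of n_steps."""

    dt: float
    n_steps: int
    initial_state: np.ndarray | float = 0.0
    seed: int = 0
    burn_in: int | None = None

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.initial_state = np.atleast_1d(
            np.asarray(self.initial_state, dtype=float)
        )
        if self.burn_in is None:
            self.burn_in = self.n_steps // 100
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")


@dataclass
class ColoredPitchforkParams:
    """dx/dt = lam*x - mu*x^3 + eta;  d(eta)/dt = -alpha*eta + sigma_eta*w."""

    lam: float = 1.0
    mu: float = 1.0
    alpha: float = 100.0
    sigma_eta: float = 50.0

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass
class DoubleWellParams:
    """Second-order particle with damping 2: x'' + 2x' = eps*x - x^3 + sigma*w."""

    epsilon: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class WakeSurrogateParams:
    """2D Cartesian realization of dr = (lam*r - mu*r^3 + a(r)/r)dt + sigma(r)dW
    with sigma(r) = sigma0 + sigma1*r^2."""

    lam: float = 1.0
    mu: float = 1.0
    sigma0: float = 0.3
    sigma1: float = 0.15

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.sigma0 <= 0 or self.sigma1 < 0:
            raise ValueError("need sigma0 > 0 and sigma1 >= 0 for sigma(r) > 0")


def _finish(out: np.ndarray, fail: int, spec: SimSpec, label: str) -> TimeSeries:
    if fail >= 0:
        raise SimulationError(
            f"{label}: non-finite state at step {fail} "
            f"(dt={spec.dt}, seed={spec.seed})"
        )
    return TimeSeries(values=out[spec.burn_in:], dt=spec.dt, label=label)


def euler_maruyama(model: LangevinModel, spec: SimSpec) -> TimeSeries:
    """Integrate a library model: x_{k+1} = x_k + f dt + sigma sqrt(dt) z_k.

    Library evaluation is used without domain clamping; a trajectory leaving
    the region where the model is well behaved fails with the step index.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_steps)
    x0 = float(spec.initial_state[0])
    out, fail = _kernels.em_poly(
        x0,
        spec.dt,
        np.asarray(model.drift_library.degrees, dtype=np.int64),
        np.asarray(model.drift_coeffs, dtype=float),
        np.asarray(model.diffusion_library.degrees, dtype=np.int64),
        np.asarray(model.diffusion_coeffs, dtype=float),
        model.polar_ito_term,
        noise,
    )
    return _finish(out, fail, spec, "euler_maruyama")


def simulate_colored_pitchfork(
    params: ColoredPitchforkParams, spec: SimSpec
) -> TimeSeries:
    """Cubic normal form driven by Ornstein-Uhlenbeck forcing; returns x only.

    Initial state is (x0, eta0); eta0 defaults to 0 when only x0 is given.
    One standard-normal draw per step, consumed by the eta update.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_steps)
    x0 = float(spec.initial_state[0])
    eta0 = float(spec.initial_state[1]) if spec.initial_state.size > 1 else 0.0
    out, fail = _kernels.em_colored_pitchfork(
        x0, eta0, params.lam, params.mu, params.alpha, params.sigma_eta,
        spec.dt, noise,
    )
    return _finish(out, fail, spec, "colored_pitchfork")


def simulate_double_well(params: DoubleWellParams, spec: SimSpec) -> TimeSeries:
    """Second-order double-well particle; returns the position only.

    Initial state is (x0, v0); v0 defaults to 0.  One draw per step on the
    velocity equation.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_steps)
    x0 = float(spec.initial_state[0])
    v0 = float(spec.initial_state[1]) if spec.initial_state.size > 1 else 0.0
    out, fail = _kernels.em_double_well(
        x0, v0, params.epsilon, params.sigma, spec.dt, noise
    )
    return _finish(out, fail, spec, "double_well")


def simulate_wake_surrogate(
    params: WakeSurrogateParams, spec: SimSpec
) -> TimeSeries:
    """Radial amplitude of the symmetric 2D pitchfork with isotropic noise.

    Simulating in Cartesian coordinates realizes the Ito a(r)/r drift term
    exactly without touching the singular radial equation.  Initial state is
    (x0, y0); y0 defaults to 0.  Two draws per step: x first, then y.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_steps, 2))
    x0 = float(spec.initial_state[0])
    y0 = float(spec.initial_state[1]) if spec.initial_state.size > 1 else 0.0
    out, fail = _kernels.em_wake_2d(
        x0, y0, params.lam, params.mu, params.sigma0, params.sigma1,
        spec.dt, noise,
    )
    return _finish(out, fail, spec, "wake_surrogate")


def dwell_times(ts: TimeSeries, upper: float, lower: float) -> np.ndarray:
    """Durations between hysteresis switches.

    The detector switches to the + phase on crossing ``upper`` and to the -
    phase on crossing ``lower``; returns the durations of completed phases.
    An empty array (no switches) is a valid result.
    """
    if not upper > lower:
        raise ValueError("need upper > lower")
    x = ts.values
    s = np.zeros(x.size, dtype=np.int8)
    s[x >= upper] = 1
    s[x <= lower] = -1
    idx = np.nonzero(s)[0]
    if idx.size == 0:
        return np.empty(0)
    states = s[idx]
    change = np.concatenate(([True], states[1:] != states[:-1]))
    switch_idx = idx[change]
    if switch_idx.size < 2:
        return np.empty(0)
    return np.diff(switch_idx) * ts.dt


def power_spectrum(
    ts: TimeSeries, segment_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch periodogram (Hann taper, 50% overlap)."""
    if segment_length > len(ts):
        raise ValueError(
            f"segment_length {segment_length} > series length {len(ts)}"
        )
    freqs, power = signal.welch(
        ts.values,
        fs=1.0 / ts.dt,
        window="hann",
        nperseg=segment_length,
        noverlap=segment_length // 2,
    )
    return freqs, power
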