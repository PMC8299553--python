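import numpy as np
import pytest
from scipy import signal

from sdefit import (
    FunctionLibrary,
    Grid1D,
    LangevinModel,
    TimeSeries,
    build_polynomial_library,
)


def make_model(drift_coeffs, diffusion_coeffs, drift_degree=3,
               drift_parity="odd", diffusion_degree=0,
               diffusion_parity="all", polar=False, domain=None):
    """Convenience builder for monomial-library models."""
    drift = build_polynomial_library(drift_degree, drift_parity, "drift")
    diff = build_polynomial_library(diffusion_degree, diffusion_parity,
                                    "diffusion")
    return LangevinModel(
        drift_library=drift,
        drift_coeffs=np.asarray(drift_coeffs, dtype=float),
        diffusion_library=diff,
        diffusion_coeffs=np.asarray(diffusion_coeffs, dtype=float),
        polar_ito_term=polar,
        domain=domain,
    )


@pytest.fixture
def cubic_model():
    """dx = (x - x^3) dt + 0.5 dW."""
    return make_model([1.0, -1.0], [0.5])


@pytest.fixture
def ou_model():
    """dx = -x dt + sqrt(2) dW; stationary N(0, 1)."""
    return make_model([-1.0], [np.sqrt(2.0)], drift_degree=1)


def ar1_series(n, rho, innov_std, seed, dt):
    """Exact AR(1) sampler via an IIR filter (fast, vectorized)."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n) * innov_std
    values = signal.lfilter([1.0], [1.0, -rho], noise)
    return TimeSeries(values=values, dt=dt)


def exact_ou_series(n, theta, sigma, dt, seed):
    """Exact-in-distribution OU samples at spacing dt (stationary start)."""
    rho = np.exp(-theta * dt)
    stat_var = sigma**2 / (2 * theta)
    innov_std = np.sqrt(stat_var * (1 - rho**2))
    return ar1_series(n, rho, innov_std, seed, dt)
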