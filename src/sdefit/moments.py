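"""Time-series containers, binning, and empirical conditional-moment estimates.

The first and second conditional moments are the per-bin sample means of the
increment ``D = x(t + tau) - x(t)`` and of ``D**2`` (raw, uncentred second
moment) over transition pairs of the subsampled series, conditioned on the
bin containing the start point.  Uncertainty weights are inverse squared
standard errors of the bin statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EstimationError",
    "TimeSeries",
    "SamplingPlan",
    "Grid1D",
    "BinnedMoments",
    "EmpiricalPDF",
    "MarkovDiagnostic",
    "subsample",
    "estimate_moments",
    "empirical_pdf",
    "markov_scan",
]

_EPS = np.finfo(float).eps


class EstimationError(RuntimeError):
    """Raised when no usable statistics can be extracted from the data."""


@dataclass
class TimeSeries:
    """Uniformly sampled scalar trajectory."""

    values: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("time series must have length >= 2")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        self.dt = float(self.dt)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass(frozen=True)
class SamplingPlan:
    """Subsampling stride; the sampling interval becomes tau = stride * dt."""

    stride: int

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    def tau(self, dt: float) -> float:
        return self.stride * dt


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1D bin grid."""

    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.size < 2:
            raise ValueError("grid needs at least 2 edges")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("grid edges must be strictly increasing")
        h = widths[0]
        if not np.allclose(widths, h, rtol=1e-9, atol=1e-12 * abs(h)):
            raise ValueError("grid must be uniform")

    @classmethod
    def uniform(cls, lo: float, hi: float, n_bins: int) -> "Grid1D":
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not lo < hi:
            raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
        return cls(edges=np.linspace(lo, hi, n_bins + 1))

    @classmethod
    def from_data(
        cls,
        values: np.ndarray,
        n_bins: int = 40,
        trim: tuple[float, float] = (0.05, 99.95),
    ) -> "Grid1D":
        """Grid spanning the trimmed percentile range of the data.

        Default trims to the 0.05th-99.95th percentiles: robust to rare
        excursions while covering the stationary support.
        """
        values = np.asarray(values, dtype=float)
        lo, hi = np.percentile(values, trim)
        if not lo < hi:  # (near-)constant data
            pad = max(abs(lo) * 1e-3, 1e-6)
            lo, hi = lo - pad, hi + pad
        return cls.uniform(lo, hi, n_bins)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def h(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_index(self, x: np.ndarray) -> np.ndarray:
        """Half-open binning [edge_i, edge_{i+1}); final edge closed.

        Out-of-grid points get index -1.
        """
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.edges, x, side="right") - 1
        idx[x == self.edges[-1]] = self.n_bins - 1
        out = (x < self.edges[0]) | (x > self.edges[-1])
        idx[out] = -1
        return idx


@dataclass
class BinnedMoments:
    """Per-bin empirical finite-time conditional moments with weights."""

    grid: Grid1D
    tau: float
    m1: np.ndarray
    m2: np.ndarray
    counts: np.ndarray
    weights1: np.ndarray
    weights2: np.ndarray
    valid: np.ndarray
    n_dropped: int = 0


@dataclass
class EmpiricalPDF:
    """Normalized histogram density on grid centers."""

    grid: Grid1D
    density: np.ndarray
    n_dropped: int = 0


@dataclass
class MarkovDiagnostic:
    strides: list
    increment_autocorr: np.ndarray
    recommended_stride: int
    threshold: float


def subsample(ts: TimeSeries, plan: SamplingPlan) -> TimeSeries:
    """Every stride-th sample, with dt scaled accordingly."""
    if plan.stride >= len(ts):
        raise ValueError(
            f"stride {plan.stride} >= series length {len(ts)}"
        )
    return TimeSeries(
        values=ts.values[:: plan.stride],
        dt=ts.dt * plan.stride,
        label=ts.label,
    )


def estimate_moments(
    ts: TimeSeries,
    grid: Grid1D,
    plan: SamplingPlan,
    min_count: int = 10,
    uniform_weights: bool = False,
) -> BinnedMoments:
    """Bin subsampled transition pairs and estimate conditional moments.

    For each consecutive pair ``(x_k, x_{k+1})`` of the subsampled series the
    increment is assigned to the bin containing ``x_k``.  ``m1`` and ``m2``
    are per-bin means of the increment and its square.  Bins with fewer than
    ``min_count`` pairs are marked invalid and get zero weight.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sub = subsample(ts, plan)
    x0 = sub.values[:-1]
    delta = np.diff(sub.values)
    idx = grid.bin_index(x0)
    keep = idx >= 0
    n_dropped = int(np.sum(~keep))
    idx, delta = idx[keep], delta[keep]

    nb = grid.n_bins
    counts = np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore"):
        s1 = np.bincount(idx, weights=delta, minlength=nb)
        s2 = np.bincount(idx, weights=delta**2, minlength=nb)
        s4 = np.bincount(idx, weights=delta**4, minlength=nb)
    valid = counts >= min_count
    if not np.any(valid):
        raise EstimationError("no bins reached min_count")

    m1 = np.zeros(nb)
    m2 = np.zeros(nb)
    nz = counts > 0
    m1[nz] = s1[nz] / counts[nz]
    m2[nz] = s2[nz] / counts[nz]

    # per-bin sample variances of delta and delta^2 (ddof=1 where possible)
    var1 = np.zeros(nb)
    var2 = np.zeros(nb)
    gt1 = counts > 1
    var1[gt1] = (s2[gt1] - counts[gt1] * m1[gt1] ** 2) / (counts[gt1] - 1)
    var2[gt1] = (s4[gt1] - counts[gt1] * m2[gt1] ** 2) / (counts[gt1] - 1)
    var1 = np.maximum(var1, 0.0)
    var2 = np.maximum(var2, 0.0)

    if uniform_weights:
        w1 = valid.astype(float)
        w2 = valid.astype(float)
    else:
        w1 = np.where(valid, counts / np.maximum(var1, _EPS), 0.0)
        w2 = np.where(valid, counts / np.maximum(var2, _EPS), 0.0)

    return BinnedMoments(
        grid=grid,
        tau=plan.tau(ts.dt),
        m1=m1,
        m2=m2,
        counts=counts,
        weights1=w1,
        weights2=w2,
        valid=valid,
        n_dropped=n_dropped,
    )


def empirical_pdf(ts: TimeSeries, grid: Grid1D) -> EmpiricalPDF:
    """Normalized histogram of the series on the grid.

    Samples outside the grid are dropped; their count is reported on the
    returned object.
    """
    counts, _ = np.histogram(ts.values, bins=grid.edges)
    inside = counts.sum()
    if inside == 0:
        raise EstimationError("all samples fall outside the grid")
    density = counts / (inside * grid.h)
    return EmpiricalPDF(
        grid=grid, density=density, n_dropped=len(ts) - int(inside)
    )


def _lag1_autocorr(d: np.ndarray) -> float:
    d = d - d.mean()
    denom = np.dot(d, d)
    if denom <= 0:
        return 0.0
    num = np.dot(d[:-1], d[1:])
    # normalize by full variance: bounded in [-1, 1] for long series
    return float(np.clip(num / denom, -1.0, 1.0))


def markov_scan(
    ts: TimeSeries, strides: list, threshold: float = 0.05
) -> MarkovDiagnostic:
    """Lag-1 autocorrelation of subsampled increments, per stride.

    The recommended stride is the smallest one whose increment
    autocorrelation magnitude falls below ``threshold`` (a simple proxy for
    the scale at which unresolved forcing has decorrelated).  If no stride
    qualifies, the stride with the smallest magnitude is returned.
    """
    if len(strides) == 0:
        raise ValueError("stride list must be nonempty")
    strides = sorted(int(s) for s in strides)
    acs = np.empty(len(strides))
    for i, s in enumerate(strides):
        sub = subsample(ts, SamplingPlan(s))
        if len(sub) < 3:
            raise ValueError(f"stride {s} leaves too few samples")
        acs[i] = _lag1_autocorr(np.diff(sub.values))
    below = np.abs(acs) < threshold
    if np.any(below):
        rec = strides[int(np.argmax(below))]
    else:
        rec = strides[int(np.argmin(np.abs(acs)))]
    return MarkovDiagnostic(
        strides=strides,
        increment_autocorr=acs,
        recommended_stride=rec,
        threshold=threshold,
    )
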