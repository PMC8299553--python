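"""Parameterized scalar Langevin models built from candidate function libraries.

A model is ``dx/dt = f(x) + sigma(x) w(t)`` with drift ``f`` and noise
amplitude ``sigma`` expressed as linear combinations of library terms.  The
effective diffusion is ``a(x) = sigma(x)**2 / 2``.  Radial-coordinate models
carry an additional structural, coefficient-free drift contribution
``a(x)/x`` (the Ito term from a polar change of variables); it is recomputed
from the current diffusion coefficients at every evaluation and is never a
sparsification candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "InfeasibleModelError",
    "FunctionTerm",
    "FunctionLibrary",
    "LangevinModel",
    "monomial_term",
    "build_polynomial_library",
    "evaluate_drift",
    "evaluate_diffusion",
]


class DomainError(ValueError):
    """Evaluation point outside the model domain."""


class InfeasibleModelError(RuntimeError):
    """sigma(x) <= 0 somewhere on the queried points.

    Non-fatal signal: the fitting layer converts it into a finite penalty.
    """


@dataclass(frozen=True)
class FunctionTerm:
    """A single candidate function.

    The evaluator must be a deterministic, finite, pure map on the model
    domain.  ``degree`` is the polynomial degree used for parity filtering
    and tie-breaking during model selection.
    """

    name: str
    degree: int
    kind: str  # "drift" or "diffusion"
    evaluator: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.evaluator(np.asarray(x, dtype=float))


def monomial_term(degree: int, kind: str) -> FunctionTerm:
    """Build the monomial term x**degree."""
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    if degree == 0:
        name = "1"

        def ev(x):
            return np.ones_like(np.asarray(x, dtype=float))

    else:
        name = "x" if degree == 1 else f"x^{degree}"

        def ev(x, _d=degree):
            return np.asarray(x, dtype=float) ** _d

    return FunctionTerm(name=name, degree=degree, kind=kind, evaluator=ev)


@dataclass(frozen=True)
class FunctionLibrary:
    """Ordered collection of candidate terms with a parity constraint."""

    terms: tuple[FunctionTerm, ...]
    parity: str = "all"  # "all" | "odd" | "even"

    def __post_init__(self):
        if len(self.terms) == 0:
            raise ValueError("library must be nonempty")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"term names must be unique, got {names}")
        if self.parity == "odd" and any(t.degree % 2 == 0 for t in self.terms):
            raise ValueError("odd-parity library contains even-degree terms")
        if self.parity == "even" and any(t.degree % 2 == 1 for t in self.terms):
            raise ValueError("even-parity library contains odd-degree terms")
        if self.parity not in ("all", "odd", "even"):
            raise ValueError(f"unknown parity {self.parity!r}")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(t.degree for t in self.terms)

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Evaluate every term at x; shape (len(x), n_terms)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.column_stack([t(x) for t in self.terms])


def build_polynomial_library(
    max_degree: int, parity: str = "all", kind: str = "drift"
) -> FunctionLibrary:
    """Monomials x^0 ... x^max_degree filtered by parity, ordered by degree."""
    if max_degree < 0:
        raise ValueError(f"max_degree must be >= 0, got {max_degree}")
    if parity == "odd":
        degrees = range(1, max_degree + 1, 2)
    elif parity == "even":
        degrees = range(0, max_degree + 1, 2)
    elif parity == "all":
        degrees = range(0, max_degree + 1)
    else:
        raise ValueError(f"unknown parity {parity!r}")
    degrees = list(degrees)
    if not degrees:
        raise ValueError(
            f"no terms with parity={parity!r} and max_degree={max_degree}"
        )
    return FunctionLibrary(
        terms=tuple(monomial_term(d, kind) for d in degrees), parity=parity
    )


@dataclass
class LangevinModel:
    """Drift/diffusion model with named-coefficient structure.

    ``domain`` is a closed interval; evaluation outside it is an error, not
    an extrapolation (Fokker-Planck discretizations are only meaningful on
    the grid they were built for).  ``domain=None`` disables the check.
    """

    drift_library: FunctionLibrary
    drift_coeffs: np.ndarray
    diffusion_library: FunctionLibrary
    diffusion_coeffs: np.ndarray
    polar_ito_term: bool = False
    domain: tuple[float, float] | None = None

    def __post_init__(self):
        self.drift_coeffs = np.atleast_1d(
            np.asarray(self.drift_coeffs, dtype=float)
        )
        self.diffusion_coeffs = np.atleast_1d(
            np.asarray(self.diffusion_coeffs, dtype=float)
        )
        if len(self.drift_coeffs) != len(self.drift_library):
            raise ValueError(
                f"drift_coeffs length {len(self.drift_coeffs)} != "
                f"library length {len(self.drift_library)}"
            )
        if len(self.diffusion_coeffs) != len(self.diffusion_library):
            raise ValueError(
                f"diffusion_coeffs length {len(self.diffusion_coeffs)} != "
                f"library length {len(self.diffusion_library)}"
            )
        if self.domain is not None:
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError(f"empty domain {self.domain}")
            if self.polar_ito_term and lo <= 0:
                raise ValueError(
                    "polar models require a strictly positive domain"
                )
            self.domain = (float(lo), float(hi))

    # -- coefficient plumbing -------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.drift_coeffs) + len(self.diffusion_coeffs)

    def coeff_vector(self) -> np.ndarray:
        return np.concatenate([self.drift_coeffs, self.diffusion_coeffs])

    def with_coeff_vector(self, theta: np.ndarray) -> "LangevinModel":
        theta = np.asarray(theta, dtype=float)
        nf = len(self.drift_library)
        if theta.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} coefficients, got {theta.size}"
            )
        return replace(
            self, drift_coeffs=theta[:nf].copy(),
            diffusion_coeffs=theta[nf:].copy(),
        )

    def with_domain(self, domain: tuple[float, float]) -> "LangevinModel":
        return replace(self, domain=domain)

    @property
    def term_labels(self) -> tuple[str, ...]:
        """Namespaced labels for every free coefficient (drift then diffusion)."""
        return tuple(f"drift:{n}" for n in self.drift_library.names) + tuple(
            f"diff:{n}" for n in self.diffusion_library.names
        )

    # -- evaluation -----------------------------------------------------------

    def _check_domain(self, x: np.ndarray) -> None:
        if self.domain is None:
            return
        lo, hi = self.domain
        tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
        if np.any(x < lo - tol) or np.any(x > hi + tol):
            raise DomainError(
                f"evaluation points outside model domain [{lo}, {hi}]"
            )

    def sigma(self, x: np.ndarray, check_positive: bool = True) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        s = self.diffusion_library.design_matrix(x) @ self.diffusion_coeffs
        if check_positive and np.any(s <= 0):
            raise InfeasibleModelError(
                "sigma(x) <= 0 on the queried points "
                f"(min sigma = {s.min():.3g})"
            )
        return s

    def diffusion_a(self, x: np.ndarray) -> np.ndarray:
        """Effective diffusion a(x) = sigma(x)**2 / 2."""
        return 0.5 * self.sigma(x, check_positive=False) ** 2

    def drift(self, x: np.ndarray, check_domain: bool = True) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if check_domain:
            self._check_domain(x)
        f = self.drift_library.design_matrix(x) @ self.drift_coeffs
        if self.polar_ito_term:
            if np.any(x == 0):
                raise DomainError("polar Ito term is singular at x = 0")
            f = f + self.diffusion_a(x) / x
        return f

    def feasible_on(self, x: np.ndarray) -> bool:
        """True iff sigma(x) > 0 everywhere on x."""
        return bool(np.all(self.sigma(x, check_positive=False) > 0))

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "drift": [
                {"name": t.name, "degree": t.degree, "coeff": float(c)}
                for t, c in zip(self.drift_library.terms, self.drift_coeffs)
            ],
            "diffusion": [
                {"name": t.name, "degree": t.degree, "coeff": float(c)}
                for t, c in zip(
                    self.diffusion_library.terms, self.diffusion_coeffs
                )
            ],
            "polar_ito_term": bool(self.polar_ito_term),
            "domain": list(self.domain) if self.domain is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LangevinModel":
        def lib_and_coeffs(entries, kind):
            terms = tuple(monomial_term(int(e["degree"]), kind) for e in entries)
            degrees = [t.degree for t in terms]
            if degrees and all(dg % 2 == 1 for dg in degrees):
                parity = "odd"
            elif degrees and all(dg % 2 == 0 for dg in degrees):
                parity = "even"
            else:
                parity = "all"
            lib = FunctionLibrary(terms=terms, parity=parity)
            return lib, np.array([float(e["coeff"]) for e in entries])

        drift_lib, drift_c = lib_and_coeffs(d["drift"], "drift")
        diff_lib, diff_c = lib_and_coeffs(d["diffusion"], "diffusion")
        domain = tuple(d["domain"]) if d.get("domain") is not None else None
        return cls(
            drift_library=drift_lib,
            drift_coeffs=drift_c,
            diffusion_library=diff_lib,
            diffusion_coeffs=diff_c,
            polar_ito_term=bool(d.get("polar_ito_term", False)),
            domain=domain,
        )


def evaluate_drift(model: LangevinModel, x: np.ndarray) -> np.ndarray:
    """Drift f(x) = Theta_f(x)' xi_f (+ a(x)/x for polar models)."""
    return model.drift(x)


def evaluate_diffusion(model: LangevinModel, x: np.ndarray) -> np.ndarray:
    """Noise amplitude sigma(x); raises InfeasibleModelError if sigma <= 0."""
    model._check_domain(np.atleast_1d(np.asarray(x, dtype=float)))
    return model.sigma(x, check_positive=True)
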