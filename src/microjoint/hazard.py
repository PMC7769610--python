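"""Hazard function with a scaled-relative-abundance link.

The event submodel extends a parametric proportional-hazards model with a
term driven by the longitudinal submodel's fitted relative abundance p(t):

    h(t | w, p(.)) = h0(t) * exp(gamma' w + alpha * phi * p(t))

where w are baseline covariates, alpha is the abundance effect size and
phi is a fixed scaling constant (phi = 10 makes the unit of alpha a 10%
change in relative abundance).  The cumulative hazard has no closed form
once p(t) varies with time, so it is computed with Gauss-Legendre
quadrature mapped to [0, t].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HazardParams",
    "QuadratureRule",
    "hazard_at",
    "cumulative_hazard",
    "survival",
    "event_loglik",
]


@dataclass
class HazardParams:
    """Parameters of the event submodel.

    Parameters
    ----------
    baseline
        Baseline hazard family, ``"exponential"`` (h0 = rate, the family
        used throughout the simulation design) or ``"weibull"``
        (h0(t) = rate * shape * t**(shape-1), for applications where the
        event hazard rises with time, e.g. delivery over gestation).
    rate
        Baseline rate lambda > 0 (Weibull: the scale-like rate parameter).
    shape
        Weibull shape k > 0; ignored (must be 1) for the exponential family.
    gamma
        Log-hazard effect sizes for the baseline covariates w.
    alpha
        Effect size of the scaled relative abundance.
    phi
        Fixed positive scaling constant for relative abundances; a constant
        of the analysis, never estimated.
    t_max
        Administrative right-censoring horizon.
    """

    baseline: str = "exponential"
    rate: float = 0.1
    shape: float = 1.0
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: float = 0.0
    phi: float = 10.0
    t_max: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline family {self.baseline!r}")
        if not self.rate > 0:
            raise ValueError("baseline rate must be > 0")
        if not self.shape > 0:
            raise ValueError("Weibull shape must be > 0")
        if self.baseline == "exponential" and self.shape != 1.0:
            raise ValueError("exponential baseline requires shape == 1")
        if not self.phi > 0:
            raise ValueError("phi must be > 0")
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))

    def baseline_hazard(self, t):
        """h0(t) for the configured family; vectorized over t."""
        t = np.asarray(t, dtype=float)
        if self.baseline == "exponential":
            return np.broadcast_to(self.rate, t.shape).copy()
        # Weibull h0 = rate * shape * t^(shape-1); guard t=0 for shape<1
        with np.errstate(divide="ignore"):
            return self.rate * self.shape * np.power(np.maximum(t, 1e-300),
                                                     self.shape - 1.0)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Legendre nodes and weights on the unit interval [0, 1].

    An integral over [0, t] is evaluated as t * sum(w_q * f(t * x_q)),
    which is exact for polynomial integrands up to degree 2Q - 1; in
    particular constants integrate exactly for any order Q >= 1.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def order(self) -> int:
        return len(self.nodes)

    @classmethod
    def gauss_legendre(cls, order: int = 15) -> "QuadratureRule":
        if order < 1:
            raise ValueError("quadrature order must be >= 1")
        x, w = np.polynomial.legendre.leggauss(order)
        return cls(nodes=(x + 1.0) / 2.0, weights=w / 2.0)

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must integrate constants exactly on [0,1]")


def _linear_predictor_term(w_i: np.ndarray, params: HazardParams) -> float:
    gamma = params.gamma
    w_i = np.atleast_1d(np.asarray(w_i, dtype=float))
    if gamma.size == 0:
        return 0.0
    if w_i.shape[-1] != gamma.shape[0]:
        raise ValueError(
            f"covariate vector of length {w_i.shape[-1]} does not match "
            f"gamma of length {gamma.shape[0]}")
    return float(w_i @ gamma)


def hazard_at(t, w_i, rel_abund: Callable, params: HazardParams):
    """Hazard h(t) = h0(t) exp(gamma'w + alpha*phi*p(t)); vectorized over t.

    ``rel_abund`` is a callable returning the (model-implied) relative
    abundance p(t) >= 0 at arbitrary times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    p = np.asarray(rel_abund(t), dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("rel_abund(t) returned non-finite values")
    lin = _linear_predictor_term(w_i, params)
    return params.baseline_hazard(t) * np.exp(lin + params.alpha * params.phi * p)


def cumulative_hazard(t: float, w_i, rel_abund: Callable,
                      params: HazardParams,
                      rule: QuadratureRule | None = None) -> float:
    """Gauss-Legendre approximation of H(t) = int_0^t h(u) du."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    if rule is None:
        rule = QuadratureRule.gauss_legendre()
    u = t * rule.nodes
    h = hazard_at(u, w_i, rel_abund, params)
    return float(t * np.dot(rule.weights, h))


def survival(t: float, w_i, rel_abund: Callable, params: HazardParams,
             rule: QuadratureRule | None = None) -> float:
    """S(t) = exp(-H(t))."""
    return float(np.exp(-cumulative_hazard(t, w_i, rel_abund, params, rule)))


def event_loglik(T: float, delta: int, w_i, rel_abund: Callable,
                 params: HazardParams,
                 rule: QuadratureRule | None = None) -> float:
    """Log-likelihood contribution delta*log h(T) - H(T) of one subject."""
    if not T > 0:
        raise ValueError("event/censoring time must be > 0")
    H = cumulative_hazard(T, w_i, rel_abund, params, rule)
    if delta:
        return float(np.log(hazard_at(T, w_i, rel_abund, params))) - H
    return -H
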