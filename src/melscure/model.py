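"""Deterministic model functions for the joint MELS / mixture-cure model.

The longitudinal mean follows a three-parameter logistic curve in time
(days since conception),

    mu_i(t) = a_i1 / (1 + exp{-(t - a_i2) / a_i3}),   a_ik = exp{theta_k + b_ik},

so ``a_i1`` is the subject's log10 beta-HCG plateau, ``a_i2`` the inflection
day and ``a_i3`` the growth time-scale.  The residual SD is subject-specific
(mixed-effects location scale, "MELS"): sigma_i = exp{theta4 + b_i4} when the
subject has two or more measurements, exp{theta4} otherwise.  The reference
variant instead uses a single global sigma.

Susceptible subjects face a Weibull proportional hazard with the current
longitudinal mean and (MELS only) the subject's error variance as shared
terms,

    h_i(t) = phi * t^(phi-1) * exp{lam + alpha1 * mu_i(t) + alpha2 * sigma_i^2},

while a cured fraction eta = logistic(nu) never experiences the event.  The
cumulative hazard has no closed form because mu_i(t) is time-varying; it is
computed with fixed-order Gauss-Legendre quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Parameters",
    "RandomEffects",
    "Subject",
    "logistic_mean",
    "error_sd",
    "cure_fraction",
    "hazard",
    "cumulative_hazard",
    "survival",
    "population_survival",
    "DEFAULT_QUAD_ORDER",
]

DEFAULT_QUAD_ORDER = 20


@dataclass(frozen=True)
class Parameters:
    """Population parameter vector for either model variant.

    The MELS variant carries ``theta4`` (log error-SD intercept) and
    ``alpha2`` (variance-sharing association); the reference variant instead
    carries a single global ``sigma`` and no variance sharing.
    """

    theta1: float
    theta2: float
    theta3: float
    nu: float
    lam: float
    phi: float
    alpha1: float
    Sigma: np.ndarray
    theta4: Optional[float] = None
    alpha2: Optional[float] = None
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3", "nu", "lam", "phi", "alpha1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name!r}")
        if self.phi <= 0:
            raise ValueError("Weibull shape phi must be positive")
        is_mels = self.theta4 is not None
        if is_mels and (self.alpha2 is None or self.sigma is not None):
            raise ValueError("MELS variant requires theta4 and alpha2 and no global sigma")
        if not is_mels and (self.sigma is None or self.alpha2 is not None):
            raise ValueError("reference variant requires a global sigma and no theta4/alpha2")
        if not is_mels and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        Sigma = np.asarray(self.Sigma, dtype=float)
        object.__setattr__(self, "Sigma", Sigma)
        p = 4 if is_mels else 3
        if Sigma.shape != (p, p):
            raise ValueError(f"Sigma must be {p}x{p} for this variant, got {Sigma.shape}")
        if not np.allclose(Sigma, Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")

    @property
    def variant(self) -> Literal["reference", "mels"]:
        return "mels" if self.theta4 is not None else "reference"

    @property
    def n_random_effects(self) -> int:
        return 4 if self.variant == "mels" else 3


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level deviations; ``b4`` (log error-SD deviation) is MELS-only."""

    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0

    @classmethod
    def from_array(cls, b: Sequence[float]) -> "RandomEffects":
        b = np.asarray(b, dtype=float)
        if b.shape not in ((3,), (4,)):
            raise ValueError("random-effects vector must have length 3 or 4")
        return cls(*b) if b.size == 4 else cls(b[0], b[1], b[2], 0.0)

    def as_array(self, p: int) -> np.ndarray:
        if p == 3:
            return np.array([self.b1, self.b2, self.b3])
        return np.array([self.b1, self.b2, self.b3, self.b4])


@dataclass(frozen=True)
class Subject:
    """One woman's longitudinal record plus her survival observation.

    ``censoring`` is ``"interval"`` when fetal death is known to lie in
    ``(t_left, t_right]`` and ``"right"`` when she is event-free at
    ``t_cens`` (by convention her last measurement time).
    """

    id: str
    times: np.ndarray
    y: np.ndarray
    censoring: Literal["interval", "right"]
    t_left: Optional[float] = None
    t_right: Optional[float] = None
    t_cens: Optional[float] = None

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "y", y)
        if times.size != y.size or times.size < 1:
            raise ValueError(f"subject {self.id}: times and y must have equal length >= 1")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"subject {self.id}: times must be strictly increasing")
        if np.any(times < 0) or not np.all(np.isfinite(times)):
            raise ValueError(f"subject {self.id}: times must be finite and non-negative")
        if self.censoring == "interval":
            if self.t_left is None or self.t_right is None:
                raise ValueError(f"subject {self.id}: interval censoring needs t_left and t_right")
            if not (0 <= self.t_left < self.t_right):
                raise ValueError(f"subject {self.id}: need 0 <= t_left < t_right")
        elif self.censoring == "right":
            if self.t_cens is None:
                raise ValueError(f"subject {self.id}: right censoring needs t_cens")
        else:
            raise ValueError(f"subject {self.id}: unknown censoring {self.censoring!r}")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


def _abc(params: Parameters, b: RandomEffects) -> tuple[float, float, float]:
    return (
        np.exp(params.theta1 + b.b1),
        np.exp(params.theta2 + b.b2),
        np.exp(params.theta3 + b.b3),
    )


def logistic_mean(params: Parameters, b: RandomEffects, t):
    """Three-parameter logistic mean trajectory at time ``t`` (days).

    Vectorized over ``t``.  Strictly increasing with asymptote
    ``exp(theta1 + b1)`` and half-asymptote at ``t = exp(theta2 + b2)``.
    """
    a1, a2, a3 = _abc(params, b)
    return a1 * expit((np.asarray(t, dtype=float) - a2) / a3)


def error_sd(params: Parameters, b: RandomEffects, n_i: int) -> float:
    """Residual SD of subject ``i`` with ``n_i`` longitudinal measurements.

    MELS: exp(theta4) for a single measurement (b4 cannot be informed),
    exp(theta4 + b4) otherwise.  Reference variant: the global sigma.
    """
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    if params.variant == "reference":
        return float(params.sigma)
    return float(np.exp(params.theta4 + (b.b4 if n_i >= 2 else 0.0)))


def cure_fraction(nu: float) -> float:
    """Cure probability eta = 1 / (1 + exp(-nu)) of the incidence model."""
    if not np.isfinite(nu):
        raise ValueError("nu must be finite")
    return float(expit(nu))


def hazard(t, params: Parameters, b: RandomEffects, n_i: int = 2):
    """Latency hazard phi*t^(phi-1)*exp{lam + alpha1*mu(t) + alpha2*sigma^2}.

    The reference variant is the alpha2-term-absent special case.
    Vectorized over ``t``; all times must be positive.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    lin = params.lam + params.alpha1 * logistic_mean(params, b, t)
    if params.variant == "mels":
        lin = lin + params.alpha2 * error_sd(params, b, n_i) ** 2
    return params.phi * t ** (params.phi - 1.0) * np.exp(lin)


from functools import lru_cache


@lru_cache(maxsize=8)
def _gauss_legendre(order: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


def cumulative_hazard(t, params: Parameters, b: RandomEffects, n_i: int = 2,
                      quad_order: int = DEFAULT_QUAD_ORDER):
    """H(t) = int_0^t h(u) du by Gauss-Legendre quadrature on [0, t].

    The integrand (power-law baseline times a logistic-in-time factor) is
    smooth, so a modest fixed order (default 20) is accurate to ~1e-8
    relative error for the parameter ranges of interest.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative hazard requires t >= 0")
    x, w = _gauss_legendre(quad_order)
    tt = np.atleast_1d(t)
    half = tt[..., None] / 2.0
    u = half * (x + 1.0)  # nodes in (0, t), endpoints excluded
    with np.errstate(divide="ignore", invalid="ignore"):
        hu = np.where(u > 0, hazard(np.where(u > 0, u, 1.0), params, b, n_i), 0.0)
    H = half[..., 0] * (hu * w).sum(axis=-1)
    H = np.where(tt == 0.0, 0.0, H)
    return H if t.ndim else float(H[0])


def survival(t, params: Parameters, b: RandomEffects, n_i: int = 2,
             quad_order: int = DEFAULT_QUAD_ORDER):
    """Latency survival S(t) = exp{-H(t)} for a susceptible subject."""
    return np.exp(-cumulative_hazard(t, params, b, n_i, quad_order))


def population_survival(t, params: Parameters, b: RandomEffects, n_i: int = 2,
                        quad_order: int = DEFAULT_QUAD_ORDER):
    """Cure-adjusted survival eta + (1 - eta) * S(t); plateaus at eta."""
    eta = cure_fraction(params.nu)
    return eta + (1.0 - eta) * survival(t, params, b, n_i, quad_order)
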