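"""Shared parameterization of the delayed Cdk1--APC/C negative-feedback oscillator.

The model follows a single concentration, active Cdk1-cyclin B, produced at a
constant rate ``k_s`` (nM/min) and degraded through APC/C-mediated cyclin
destruction with rate constant ``b_deg`` (1/min).  APC/C activity is an
ultrasensitive Hill function of Cdk1 activity evaluated some time in the
past; the alternative delay formulations (discrete, Gamma-distributed,
state-dependent) live in sibling modules and all share the objects defined
here: the parameter container, the Hill response with threshold ``K`` and
exponent ``m``, the dimensionless balance ratio ``c = k_s / (b_deg * K)``
and the unique fixed point of the feedback loop.

``m`` may be ``math.inf``, which selects the relay (on/off) limit of the
response; ``c`` then fully determines the fixed point (Cdk1* = K,
APC/C* = c) provided 0 < c < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .errors import DomainError, NoFixedPointError

__all__ = [
    "OscillatorParams",
    "FixedPoint",
    "hill",
    "hill_slope",
    "dimensionless_c",
    "fixed_point",
]

#: Sentinel for the relay (infinitely steep response) limit.
INFINITE_M = math.inf


def hill(x, K: float, m: float):
    """Ultrasensitive APC/C response ``x^m / (K^m + x^m)``.

    Evaluated in log space as ``expit(m * log(x / K))`` so that arbitrarily
    large exponents never overflow.  For ``m = inf`` the response is the unit
    step: 0 below ``K``, 1 above, and 0.5 exactly at ``K`` (the pointwise
    limit of the finite-m value).

    Parameters
    ----------
    x : float or array-like
        Cdk1 activity (nM), must be >= 0.
    K : float
        Activation threshold (nM), must be > 0.
    m : float
        Hill exponent, >= 1 or ``math.inf``.
    """
    if K <= 0:
        raise DomainError(f"threshold K must be positive, got {K}")
    if not (math.isinf(m) or m >= 1):
        raise DomainError(f"Hill exponent must be >= 1 or inf, got {m}")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError("Cdk1 activity must be nonnegative")
    if math.isinf(m):
        out = np.where(arr > K, 1.0, np.where(arr == K, 0.5, 0.0))
    else:
        with np.errstate(divide="ignore"):
            out = expit(m * np.log(arr / K))
    return float(out) if arr.ndim == 0 else out


def hill_slope(x: float, K: float, m: float) -> float:
    """Derivative of :func:`hill` with respect to ``x`` (finite ``m`` only)."""
    if math.isinf(m):
        raise DomainError("hill_slope requires a finite Hill exponent")
    if x < 0:
        raise DomainError("Cdk1 activity must be nonnegative")
    if x == 0.0:
        return 1.0 / K if m == 1 else 0.0
    h = hill(x, K, m)
    return m / x * h * (1.0 - h)


@dataclass(frozen=True)
class OscillatorParams:
    """Kinetic parameters shared by every model variant.

    Attributes
    ----------
    k_s : float
        Cyclin production rate (nM/min), > 0.
    b_deg : float
        Cyclin degradation rate constant (1/min), > 0.
    K : float
        APC/C activation threshold (nM), > 0.
    m : float
        Hill exponent (>= 1), or ``math.inf`` for the relay limit.
    """

    k_s: float
    b_deg: float
    K: float
    m: float = 15.0

    def __post_init__(self) -> None:
        if self.k_s <= 0 or self.b_deg <= 0 or self.K <= 0:
            raise DomainError(
                "k_s, b_deg and K must all be positive, got "
                f"k_s={self.k_s}, b_deg={self.b_deg}, K={self.K}"
            )
        if not (math.isinf(self.m) or self.m >= 1):
            raise DomainError(f"Hill exponent must be >= 1 or inf, got {self.m}")
        if not math.isfinite(self.c) or self.c <= 0:
            raise DomainError(f"derived ratio c must be finite and positive, got {self.c}")

    @property
    def c(self) -> float:
        """Dimensionless accumulation/degradation balance ``k_s / (b_deg * K)``."""
        return self.k_s / (self.b_deg * self.K)

    def hill(self, x):
        return hill(x, self.K, self.m)

    def with_(self, **kwargs) -> "OscillatorParams":
        """Return a copy with some fields replaced."""
        fields = {"k_s": self.k_s, "b_deg": self.b_deg, "K": self.K, "m": self.m}
        fields.update(kwargs)
        return OscillatorParams(**fields)


@dataclass(frozen=True)
class FixedPoint:
    """Steady state of the feedback loop.

    ``cdk1_star`` solves ``k_s = b_deg * x * hill(x)``; ``apc_star`` is the
    APC/C activity there, equal to ``c * K / cdk1_star`` algebraically.
    """

    cdk1_star: float
    apc_star: float


def dimensionless_c(params: OscillatorParams) -> float:
    """The ratio ``c = k_s / (b_deg * K)``."""
    return params.c


def fixed_point(params: OscillatorParams, xtol: float = 1e-10) -> FixedPoint:
    """Unique steady state of the delayed feedback model.

    The steady state is independent of the delay formulation: it solves
    ``k_s = b_deg * x * hill(x)``.  Since ``x * hill(x)`` is strictly
    increasing for x > 0 the root is unique and safely bracketed.

    For ``m = inf`` the fixed point exists in the relay sense only when
    0 < c < 1, in which case Cdk1* = K and APC/C* = c; otherwise a
    :class:`~cdkosc.errors.NoFixedPointError` is raised.
    """
    c = params.c
    if math.isinf(params.m):
        if not 0.0 < c < 1.0:
            raise NoFixedPointError(
                f"relay limit requires 0 < c < 1 for a fixed point, got c={c}"
            )
        return FixedPoint(cdk1_star=params.K, apc_star=c)

    def g(x: float) -> float:
        return params.b_deg * x * hill(x, params.K, params.m) - params.k_s

    x_hi = max(10.0 * params.K, 10.0 * params.k_s / params.b_deg)
    while g(x_hi) <= 0.0:  # defensive; analysis guarantees g(x_hi) > 0 already
        x_hi *= 10.0
    root = brentq(g, 0.0, x_hi, xtol=xtol)
    return FixedPoint(cdk1_star=float(root), apc_star=float(hill(root, params.K, params.m)))
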