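"""Gamma-distributed delay: density utilities and the equivalent linear chain.

A distributed delay replaces the lagged Cdk1 activity by a weighted average
of past activities, weighted by the Gamma density

    g(tau) = a^N / (N-1)! * tau^(N-1) * exp(-a*tau)

with integer shape N and rate a (mean N/a, variance N/a^2, mode (N-1)/a).
The distributed-delay model is *exactly* equivalent to a chain of N
intermediate first-order variables (the linear chain trick), and that chain
of ODEs is the only realization used here — the history integral is never
evaluated numerically.  Fixing the mean delay tau_avg while varying N means
a = N/tau_avg; N -> infinity recovers the discrete delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels
from .core import OscillatorParams, hill
from .errors import DomainError, ResolutionError
from .trajectory import ResponseCurve, Trajectory

__all__ = [
    "GammaDelaySpec",
    "ChainState",
    "gamma_pdf",
    "simulate_distributed",
    "step_response_distributed",
]


@dataclass(frozen=True)
class GammaDelaySpec:
    """Gamma delay kernel: shape / chain length ``N`` and mean delay ``tau_avg``.

    The rate is tied to the mean exactly: ``a = N / tau_avg``.
    """

    N: int
    tau_avg: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise DomainError(f"chain length N must be a positive integer, got {self.N}")
        if self.tau_avg <= 0:
            raise DomainError(f"mean delay must be positive, got {self.tau_avg}")

    @classmethod
    def from_rate(cls, N: int, a: float) -> "GammaDelaySpec":
        if a <= 0:
            raise DomainError(f"rate a must be positive, got {a}")
        return cls(N=N, tau_avg=N / a)

    @property
    def a(self) -> float:
        return self.N / self.tau_avg

    @property
    def mean(self) -> float:
        return self.tau_avg

    @property
    def variance(self) -> float:
        return self.N / self.a ** 2

    @property
    def mode(self) -> float:
        return (self.N - 1) / self.a


@dataclass
class ChainState:
    """Initial condition for the chain: Cdk1 plus the N delayed copies."""

    cdk1: float
    y: np.ndarray = field(default_factory=lambda: np.array([]))

    def vector(self, N: int) -> np.ndarray:
        if len(self.y) == 0:
            return np.full(N + 1, float(self.cdk1))
        if len(self.y) != N:
            raise DomainError(f"chain init needs {N} copies, got {len(self.y)}")
        v = np.concatenate(([self.cdk1], np.asarray(self.y, dtype=float)))
        if np.any(v < 0):
            raise DomainError("chain state must be nonnegative")
        return v


def gamma_pdf(spec: GammaDelaySpec, tau) -> np.ndarray | float:
    """The Gamma delay density evaluated at ``tau`` (min)."""
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < 0):
        raise DomainError("delay values must be nonnegative")
    out = stats.gamma.pdf(arr, a=spec.N, scale=1.0 / spec.a)
    return float(out) if arr.ndim == 0 else out


def simulate_distributed(
    params: OscillatorParams,
    spec: GammaDelaySpec,
    init,
    t_end: float,
    dt: float | None = None,
) -> Trajectory:
    """Integrate the feedback model with Gamma-distributed delay via its chain.

    ``init`` is a :class:`ChainState` or a single Cdk1 value (all chain
    copies then start at that value, consistent with a constant
    pre-history).  The reported APC/C activity is hill(y_N).
    """
    if math.isinf(params.m):
        raise DomainError("the chain realization requires a finite Hill exponent")
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    a = spec.a
    if dt is None:
        dt = min(0.01, 0.1 / a)
    if dt > 0.1 / a + 1e-15:
        raise ResolutionError(f"dt={dt} too coarse for chain rate a={a}; require dt <= 0.1/a")
    state = init if isinstance(init, ChainState) else ChainState(cdk1=float(init))
    s0 = state.vector(spec.N)
    n_total = int(math.ceil(t_end / dt)) + 1
    x = np.empty(n_total)
    apc = np.empty(n_total)
    _kernels.chain_rk4(n_total, dt, params.k_s, params.b_deg, params.K,
                       float(params.m), a, s0, x, apc)
    t = np.arange(n_total) * dt
    return Trajectory(t=t, cdk1=x, apc=apc)


def step_response_distributed(
    spec: GammaDelaySpec,
    K: float,
    m: float,
    step_size: float,
    step_time: float = 0.0,
    t_end: float | None = None,
    dt: float | None = None,
) -> ResponseCurve:
    """APC/C output when a Cdk1 step drives the chain (no feedback).

    The last chain variable follows step_size times the Gamma CDF, so the
    Hill readout rises smoothly instead of jumping as it does with a
    discrete delay.
    """
    if step_size < 0:
        raise DomainError("step size must be nonnegative")
    a = spec.a
    if dt is None:
        dt = min(0.01, 0.1 / a)
    if t_end is None:
        t_end = step_time + spec.tau_avg + 6.0 * math.sqrt(spec.variance) + 10.0
    n_total = int(math.ceil(t_end / dt)) + 1
    i_step = int(round(step_time / dt))
    y0 = np.zeros(spec.N)
    y_out = np.empty(n_total)
    _kernels.chain_driven_rk4(n_total, dt, a, 0.0, float(step_size), i_step, y0, y_out)
    t = np.arange(n_total) * dt
    return ResponseCurve(t=t, value=hill(np.clip(y_out, 0.0, None), K, m))


def chain_step_output(spec: GammaDelaySpec, step_size: float, t_end: float,
                      dt: float | None = None) -> ResponseCurve:
    """Raw last-chain-variable response to a step at t = 0 (before the Hill
    readout); equals step_size * GammaCDF(N, a)(t) analytically."""
    a = spec.a
    if dt is None:
        dt = min(0.01, 0.1 / a)
    n_total = int(math.ceil(t_end / dt)) + 1
    y0 = np.zeros(spec.N)
    y_out = np.empty(n_total)
    _kernels.chain_driven_rk4(n_total, dt, a, 0.0, float(step_size), 0, y0, y_out)
    return ResponseCurve(t=np.arange(n_total) * dt, value=y_out)
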