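"""Closed-form period, phase durations and amplitude of the relay oscillator.

In the m -> infinity limit the feedback loop alternates between pure cyclin
accumulation (APC/C off) and exponential degradation (APC/C on), each phase
extended by exactly one delay time because the switch lags the threshold
crossing.  Solving the piecewise dynamics by hand gives

    degradation time  = tau + (1/b_deg) * ln(1 + (c/(1-c)) * b_deg * tau)
    accumulation time = tau + (1/b_deg) * ((1-c)/c) * (1 - exp(-b_deg*tau))
    x_max = K + k_s * tau
    x_min = K * (c + (1-c) * exp(-b_deg * tau))

with the period their sum.  The degradation phase is the model's M-phase
proxy and the accumulation phase the S-phase proxy.  These expressions are
validated against the independent event-driven relay solver to 1e-8 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, NoOscillationError

__all__ = [
    "RelayCycle",
    "relay_period",
    "phase_balance_curve",
    "realistic_region_scan",
    "RegionScanResult",
]


@dataclass(frozen=True)
class RelayCycle:
    """One closed-form relay cycle: period, phase durations and extrema."""

    period: float
    degradation_time: float  # M-phase proxy
    accumulation_time: float  # S-phase proxy
    x_max: float
    x_min: float


def relay_period(c: float, b_deg: float, tau: float, K: float = 32.0) -> RelayCycle:
    """Closed-form relay cycle for balance ratio ``c``, degradation rate
    ``b_deg`` (1/min) and delay ``tau`` (min).

    ``K`` only scales the amplitude (x_max, x_min); period and phase
    durations are independent of it.  Requires 0 < c < 1 (otherwise the
    relay never oscillates) and tau >= 0; tau = 0 gives a degenerate cycle
    of zero period.
    """
    if not 0.0 < c < 1.0:
        raise NoOscillationError(f"relay oscillation requires 0 < c < 1, got c={c}")
    if b_deg <= 0:
        raise DomainError("b_deg must be positive")
    if tau < 0:
        raise DomainError("tau must be nonnegative")
    bt = b_deg * tau
    deg = tau + math.log1p(c / (1.0 - c) * bt) / b_deg
    acc = tau + (1.0 - c) / c * (-math.expm1(-bt)) / b_deg
    ks = c * b_deg * K
    x_max = K + ks * tau
    x_min = K * (c + (1.0 - c) * math.exp(-bt))
    return RelayCycle(period=deg + acc, degradation_time=deg,
                      accumulation_time=acc, x_max=x_max, x_min=x_min)


def phase_balance_curve(b_deg: float, tau: float, c_grid) -> tuple[pd.DataFrame, float | None]:
    """S- and M-phase durations along a grid of ``c``, and their crossing.

    Returns a DataFrame with columns (c, s_duration, m_duration) and the
    value of c where the two phases are equally long (None if the durations
    never cross on the grid).  Equality is reached roughly at c = 1/2.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any((c_grid <= 0) | (c_grid >= 1)):
        raise DomainError("c grid must lie strictly inside (0, 1)")
    rows = [relay_period(c, b_deg, tau) for c in c_grid]
    df = pd.DataFrame({
        "c": c_grid,
        "s_duration": [r.accumulation_time for r in rows],
        "m_duration": [r.degradation_time for r in rows],
    })
    diff = df.s_duration.to_numpy() - df.m_duration.to_numpy()
    cross = None
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change):
        i = sign_change[0]
        f = lambda c: (relay_period(c, b_deg, tau).accumulation_time
                       - relay_period(c, b_deg, tau).degradation_time)
        cross = float(brentq(f, c_grid[i], c_grid[i + 1]))
    return df, cross


@dataclass
class RegionScanResult:
    """Outcome of a realistic-period region scan over (b_deg, tau)."""

    grid: pd.DataFrame  # long format: b_deg, tau, period, in_band
    tau_max: float  # largest tau with period inside the band (nan if empty)
    b_deg_at: float | None  # b_deg solving period = target at tau_at, if requested


def realistic_region_scan(
    k_s: float,
    K: float,
    b_deg_grid,
    tau_grid,
    period_band: tuple[float, float] = (20.0, 30.0),
    target_period: float | None = None,
    tau_at: float | None = None,
) -> RegionScanResult:
    """Evaluate the closed-form period over a (b_deg, tau) grid.

    Cells where the relay does not oscillate (c >= 1) get period = nan.
    ``tau_max`` is the largest delay whose period falls inside
    ``period_band`` — with a ~25 min embryonic period the band [20, 30] min
    caps the delay near 8 min.  If ``target_period`` and ``tau_at`` are
    given, the b_deg solving period(b_deg, tau_at) = target_period is also
    returned (None if the target is not bracketed on the grid range).
    """
    b_vals = np.asarray(b_deg_grid, dtype=float)
    tau_vals = np.asarray(tau_grid, dtype=float)
    lo, hi = period_band
    records = []
    for b in b_vals:
        c = k_s / (b * K)
        for tau in tau_vals:
            if 0.0 < c < 1.0 and tau >= 0:
                p = relay_period(c, b, tau, K=K).period
            else:
                p = math.nan
            records.append((b, tau, p, bool(lo <= p <= hi) if math.isfinite(p) else False))
    grid = pd.DataFrame(records, columns=["b_deg", "tau", "period", "in_band"])
    in_band = grid[grid.in_band]
    tau_max = float(in_band.tau.max()) if len(in_band) else math.nan

    b_deg_at = None
    if target_period is not None and tau_at is not None:
        def f(b: float) -> float:
            c = k_s / (b * K)
            if not 0.0 < c < 1.0:
                return math.nan
            return relay_period(c, b, tau_at, K=K).period - target_period

        candidates = [b for b in b_vals if 0.0 < k_s / (b * K) < 1.0]
        for b1, b2 in zip(candidates[:-1], candidates[1:]):
            f1, f2 = f(b1), f(b2)
            if math.isfinite(f1) and math.isfinite(f2) and f1 * f2 <= 0:
                b_deg_at = float(brentq(f, b1, b2))
                break
    return RegionScanResult(grid=grid, tau_max=tau_max, b_deg_at=b_deg_at)
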