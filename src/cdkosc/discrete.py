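"""Discrete-delay DDE simulation and the exact event-driven relay solver.

``simulate_discrete`` integrates

    d[Cdk1]/dt = k_s - b_deg * [Cdk1] * hill([Cdk1](t - tau))

by the method of steps (fixed-step RK4, cubic Hermite interpolation of the
stored past).  ``simulate_relay`` solves the m -> infinity limit exactly:
the dynamics alternate between pure accumulation (x' = k_s, APC/C off) and
exponential degradation (x' = k_s - b_deg*x, APC/C on), with switches
scheduled exactly one delay time after the lagged Cdk1 activity crosses the
threshold K.  Switch times are located in closed form, not by stepping, so
the relay solution carries no discretization error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import OscillatorParams, hill
from .errors import DomainError, ResolutionError
from .trajectory import ResponseCurve, Trajectory

__all__ = [
    "DiscreteDelaySpec",
    "simulate_discrete",
    "simulate_relay",
    "relay_period_from_trajectory",
    "step_response_discrete",
]


@dataclass(frozen=True)
class DiscreteDelaySpec:
    """A single fixed lag ``tau`` (min)."""

    tau: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise DomainError(f"delay must be nonnegative, got {self.tau}")


def _default_dt(tau: float) -> float:
    return min(0.01, tau / 100.0) if tau > 0 else 0.01


def simulate_discrete(
    params: OscillatorParams,
    delay: DiscreteDelaySpec,
    history,
    t_end: float,
    dt: float | None = None,
) -> Trajectory:
    """Integrate the discrete-delay model by the method of steps.

    Parameters
    ----------
    params : OscillatorParams
        Kinetic parameters; the Hill exponent must be finite.
    delay : DiscreteDelaySpec
        The fixed lag tau (min).
    history : float or callable
        Cdk1 activity on [-tau, 0]: a constant, or a function of time.
    t_end : float
        Final time (min).
    dt : float, optional
        Step size; defaults to min(0.01, tau/100).  Must satisfy
        dt <= tau/20 when tau > 0.
    """
    if math.isinf(params.m):
        raise DomainError("simulate_discrete requires a finite Hill exponent; "
                          "use simulate_relay for the m = inf limit")
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    tau = delay.tau
    if dt is None:
        dt = _default_dt(tau)
    if dt <= 0:
        raise DomainError("dt must be positive")
    if tau > 0 and dt > tau / 20.0 + 1e-15:
        raise ResolutionError(
            f"dt={dt} too coarse for tau={tau}; require dt <= tau/20 = {tau / 20.0}"
        )

    n_pre = int(math.ceil(tau / dt)) if tau > 0 else 0
    n_steps = int(math.ceil(t_end / dt))
    n_total = n_pre + n_steps + 1
    t = (np.arange(n_total) - n_pre) * dt

    x = np.empty(n_total)
    dx = np.zeros(n_total)
    apc = np.empty(n_total)
    if callable(history):
        x[: n_pre + 1] = [history(ti) for ti in t[: n_pre + 1]]
        if n_pre > 0:  # node derivatives of the pre-history by finite differences
            dx[: n_pre + 1] = np.gradient(x[: n_pre + 1], dt)
    else:
        x[: n_pre + 1] = float(history)
    if np.any(x[: n_pre + 1] < 0):
        raise DomainError("history must be nonnegative")

    _kernels.discrete_dde_rk4(n_pre, n_total, dt, tau, params.k_s, params.b_deg,
                              params.K, float(params.m), x, dx, apc)
    return Trajectory(t=t[n_pre:], cdk1=x[n_pre:], apc=apc[n_pre:])


def simulate_relay(
    params: OscillatorParams,
    delay: DiscreteDelaySpec,
    x0: float,
    t_end: float,
    dt_out: float = 0.01,
) -> Trajectory:
    """Exact piecewise solution of the relay (m = inf) oscillator.

    APC/C is on iff the Cdk1 activity one delay earlier exceeded K
    (strictly).  With constant pre-history equal to ``x0``, every crossing
    of K schedules a switch exactly ``tau`` later; between switches the
    dynamics are linear (off) or exponential toward c*K (on) and are
    advanced in closed form.

    For c >= 1 no relay oscillation exists; the trajectory is returned with
    ``meta['oscillating'] = False``.
    """
    if not math.isinf(params.m):
        raise DomainError("simulate_relay requires m = inf")
    if delay.tau <= 0:
        raise DomainError("the relay solver requires tau > 0")
    if x0 < 0:
        raise DomainError("x0 must be nonnegative")
    if t_end <= 0:
        raise DomainError("t_end must be positive")

    ks, b, K, tau = params.k_s, params.b_deg, params.K, delay.tau
    c = params.c
    x_inf = ks / b  # = c*K, the decay target while APC/C is on

    apc_on = x0 > K
    segments = []  # (t_start, x_start, apc_on) for dense sampling
    events: list[tuple[float, str]] = []
    pending: list[tuple[float, bool]] = []  # (time, new apc state)
    t_now, x_now = 0.0, float(x0)
    if x0 == K:
        # starting exactly at threshold: APC/C is off (rising), so the
        # upward crossing happens at t = 0 and the switch fires at tau
        events.append((0.0, "cross_up"))
        pending.append((tau, True))

    def advance(x: float, on: bool, span: float) -> float:
        if on:
            return x_inf + (x - x_inf) * math.exp(-b * span)
        return x + ks * span

    def next_crossing(x: float, on: bool) -> float | None:
        """Closed-form time (from now) of the next strict crossing of K."""
        if not on:
            if x < K:
                return (K - x) / ks
            return None  # above K and rising: no further crossing
        # decaying toward x_inf
        if x > K > x_inf:
            return math.log((x - x_inf) / (K - x_inf)) / b
        return None

    guard = 0
    while t_now < t_end:
        guard += 1
        if guard > 1_000_000:
            raise RuntimeError("relay event loop failed to terminate")
        t_toggle = pending[0][0] if pending else math.inf
        tc = next_crossing(x_now, apc_on)
        t_cross = t_now + tc if tc is not None else math.inf
        t_next = min(t_toggle, t_cross, t_end)
        segments.append((t_now, x_now, apc_on))
        x_next = advance(x_now, apc_on, t_next - t_now)
        if t_next == t_end or t_next == math.inf:
            t_now, x_now = t_end, x_next
            break
        if t_cross <= t_toggle:
            # threshold crossing: schedule the delayed switch
            going_up = not apc_on  # off => rising, on => falling
            events.append((t_cross, "cross_up" if going_up else "cross_down"))
            pending.append((t_cross + tau, going_up))
            pending.sort()
            t_now, x_now = t_cross, K
        else:
            t_now, x_now = t_toggle, x_next
            _, new_state = pending.pop(0)
            apc_on = new_state
            events.append((t_toggle, "apc_on" if new_state else "apc_off"))

    # dense sampling from the exact segments
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= t_end]
    xs = np.empty_like(t_grid)
    apcs = np.empty_like(t_grid)
    starts = np.array([s[0] for s in segments])
    idx = np.searchsorted(starts, t_grid, side="right") - 1
    idx = np.clip(idx, 0, len(segments) - 1)
    for j, (tg, i) in enumerate(zip(t_grid, idx)):
        t0, xseg, on = segments[i]
        xs[j] = advance(xseg, on, tg - t0)
        apcs[j] = 1.0 if on else 0.0

    n_up = sum(1 for _, kind in events if kind == "cross_up")
    oscillating = (0.0 < c < 1.0) and n_up >= 2
    return Trajectory(t=t_grid, cdk1=xs, apc=apcs, events=events,
                      meta={"oscillating": oscillating})


def relay_period_from_trajectory(traj: Trajectory) -> float:
    """Exact period from the relay solver's event bookkeeping.

    Uses the interval between the last two upward threshold crossings (the
    relay cycle is exactly periodic after the first crossing).
    """
    ups = [t for t, kind in traj.events if kind == "cross_up"]
    if len(ups) < 2:
        raise DomainError("trajectory contains fewer than two upward crossings")
    return ups[-1] - ups[-2]


def step_response_discrete(
    delay: DiscreteDelaySpec,
    step_time: float,
    K: float,
    m: float,
    step_level: float | None = None,
    t_end: float | None = None,
    dt: float = 0.01,
) -> ResponseCurve:
    """APC/C output when Cdk1 jumps from 0 to ``step_level`` at ``step_time``.

    In the discrete-delay model the APC/C output is exactly the Hill readout
    of the input one delay earlier, so it jumps at ``step_time + tau``.
    """
    if step_level is None:
        step_level = 2.0 * K
    if t_end is None:
        t_end = step_time + delay.tau + max(10.0, delay.tau)
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    lagged_input = np.where(t - delay.tau >= step_time, step_level, 0.0)
    return ResponseCurve(t=t, value=hill(lagged_input, K, m))
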