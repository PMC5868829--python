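"""Two-variable model with an APC/C-dependent (state-dependent) delay.

APC/C activation and inactivation need not be equally slow: activation via
multisite phosphorylation can take long (tau1), while inactivation may need
only one dephosphorylation (tau2).  The model keeps APC/C as an explicit
relaxation variable so the lag can be read off the current state:

    d[Cdk1]/dt  = k_s - b_deg * [Cdk1] * [APC/C]
    d[APC/C]/dt = beta * (hill([Cdk1](t - tau([APC/C]))) - [APC/C])
    tau(a)      = tau1 + (tau2 - tau1) * a^p / (0.5^p + a^p)

The delay switches smoothly from tau1 (APC/C low) to tau2 (APC/C high) with
Hill steepness p around the fixed half-switch activity 0.5.  For
tau1 = tau2 and large beta this reduces to the discrete-delay model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .core import OscillatorParams
from .errors import DomainError, InsufficientDataError, ResolutionError
from .features import extract_features
from .trajectory import Trajectory

__all__ = [
    "StateDependentDelaySpec",
    "tau_of_apc",
    "simulate_state_dependent",
    "zero_delay_boundary",
    "delay_pair_scan",
    "delay_budget_scan",
]


@dataclass(frozen=True)
class StateDependentDelaySpec:
    """Activation lag ``tau1``, inactivation lag ``tau2`` and the delay switch.

    ``p`` is the Hill exponent of the switch, ``switch_threshold`` the APC/C
    activity at half-switch (0.5 in the model equations) and ``beta`` the
    APC/C relaxation rate (1/min).
    """

    tau1: float
    tau2: float
    p: float = 5.0
    switch_threshold: float = 0.5
    beta: float = 5.0

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise DomainError("delays must be nonnegative")
        if self.p < 1:
            raise DomainError("switch exponent p must be >= 1")
        if not 0 < self.switch_threshold < 1:
            raise DomainError("switch threshold must lie in (0, 1)")
        if self.beta <= 0:
            raise DomainError("beta must be positive")


def tau_of_apc(apc, spec: StateDependentDelaySpec):
    """Instantaneous delay as a function of APC/C activity (in [0, 1])."""
    arr = np.asarray(apc, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError("APC/C activity must lie in [0, 1]")
    thrp = spec.switch_threshold ** spec.p
    w = arr ** spec.p / (thrp + arr ** spec.p)
    out = spec.tau1 + (spec.tau2 - spec.tau1) * w
    return float(out) if arr.ndim == 0 else out


def simulate_state_dependent(
    params: OscillatorParams,
    spec: StateDependentDelaySpec,
    history=(50.0, 0.0),
    t_end: float = 400.0,
    dt: float | None = None,
) -> Trajectory:
    """Integrate the state-dependent-delay model with RK4.

    ``history`` is a pair (cdk1, apc) used as a constant pre-history; the
    lag at each stage is evaluated from the current APC/C activity and the
    lagged Cdk1 value read from the stored past by interpolation.  The
    returned trajectory records the instantaneous delay in ``tau``.
    """
    if math.isinf(params.m):
        raise DomainError("the state-dependent model requires a finite Hill exponent")
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    x0, a0 = float(history[0]), float(history[1])
    if x0 < 0 or not 0 <= a0 <= 1:
        raise DomainError("history must satisfy cdk1 >= 0 and apc in [0, 1]")
    positive = [tau for tau in (spec.tau1, spec.tau2) if tau > 0]
    if dt is None:
        dt = min(0.02, min(positive) / 20.0) if positive else 0.02
    if positive and dt > min(min(positive), 1.0) / 20.0 + 1e-15:
        raise ResolutionError(
            f"dt={dt} too coarse; require dt <= min(tau1, tau2, 1)/20"
        )

    max_tau = max(spec.tau1, spec.tau2)
    n_pre = int(math.ceil(max_tau / dt)) + 2
    n_steps = int(math.ceil(t_end / dt))
    n_total = n_pre + n_steps + 1
    x = np.empty(n_total)
    a = np.empty(n_total)
    dxx = np.zeros(n_total)
    tau_rec = np.empty(n_total)
    x[: n_pre + 1] = x0
    a[: n_pre + 1] = a0
    tau_rec[: n_pre + 1] = tau_of_apc(a0, spec)

    _kernels.sdd_rk4(n_pre, n_total, dt, spec.tau1, spec.tau2, spec.p,
                     spec.switch_threshold, spec.beta, params.k_s, params.b_deg,
                     params.K, float(params.m), x, a, dxx, tau_rec)
    t = (np.arange(n_total) - n_pre) * dt
    return Trajectory(t=t[n_pre:], cdk1=x[n_pre:], apc=a[n_pre:],
                      tau=tau_rec[n_pre:])


def _features_or_none(traj: Trajectory, **kw):
    try:
        return extract_features(traj, **kw)
    except InsufficientDataError:
        return None


def zero_delay_boundary(
    params: OscillatorParams,
    c_values,
    tau_values,
    which: str = "tau2_zero",
    p: float = 5.0,
    beta: float = 5.0,
    t_end: float = 400.0,
    dt: float = 0.02,
) -> pd.DataFrame:
    """Oscillation classification when one of the two delays is zero.

    For each balance ratio c (b_deg is set to k_s/(c*K), holding k_s and K
    from ``params``) and each value of the remaining delay, the model is
    simulated and classified by feature extraction.  With tau2 = 0
    oscillations exist at low c and vanish at high c; tau1 = 0 gives the
    inverse picture.
    """
    if which not in ("tau1_zero", "tau2_zero"):
        raise DomainError("which must be 'tau1_zero' or 'tau2_zero'")
    rows = []
    for c in np.asarray(c_values, dtype=float):
        pars = params.with_(b_deg=params.k_s / (c * params.K))
        for tau in np.asarray(tau_values, dtype=float):
            if which == "tau2_zero":
                spec = StateDependentDelaySpec(tau1=tau, tau2=0.0, p=p, beta=beta)
            else:
                spec = StateDependentDelaySpec(tau1=0.0, tau2=tau, p=p, beta=beta)
            traj = simulate_state_dependent(pars, spec, t_end=t_end, dt=dt)
            feats = _features_or_none(traj)
            rows.append((c, tau, bool(feats.oscillating) if feats else False))
    return pd.DataFrame(rows, columns=["c", "tau", "oscillating"])


def delay_pair_scan(
    params: OscillatorParams,
    tau1_values,
    tau2_values,
    p: float = 5.0,
    beta: float = 5.0,
    t_end: float = 400.0,
    dt: float = 0.02,
    equal_tol: float = 0.10,
) -> pd.DataFrame:
    """Oscillation features over a (tau1, tau2) grid.

    Returns one row per cell with period, amplitude, S/M durations, the
    oscillation flag and ``equal_flag`` marking cells whose S- and M-phase
    durations agree within ``equal_tol`` of the period (the equal-duration
    locus).
    """
    rows = []
    for tau1 in np.asarray(tau1_values, dtype=float):
        for tau2 in np.asarray(tau2_values, dtype=float):
            spec = StateDependentDelaySpec(tau1=tau1, tau2=tau2, p=p, beta=beta)
            traj = simulate_state_dependent(params, spec, t_end=t_end, dt=dt)
            feats = _features_or_none(traj)
            if feats is None or not feats.oscillating:
                rows.append((tau1, tau2, False, math.nan, math.nan,
                             math.nan, math.nan, False))
                continue
            equal = abs(feats.s_duration - feats.m_duration) <= equal_tol * feats.period
            rows.append((tau1, tau2, True, feats.period, feats.amplitude,
                         feats.s_duration, feats.m_duration, bool(equal)))
    return pd.DataFrame(rows, columns=["tau1", "tau2", "oscillating", "period",
                                       "amplitude", "s_duration", "m_duration",
                                       "equal_flag"])


def delay_budget_scan(
    params_base: OscillatorParams,
    b_deg_values,
    tau1_values,
    tau_sum: float = 15.0,
    p: float = 5.0,
    beta: float = 5.0,
    t_end: float = 400.0,
    dt: float = 0.02,
    equal_tol: float = 0.10,
) -> pd.DataFrame:
    """Features over a (b_deg, tau1) grid with tau1 + tau2 fixed.

    Constraining the delay budget and asking for a realistic (~25 min)
    period with near-equal phases selects the degradation rate.
    """
    rows = []
    for b in np.asarray(b_deg_values, dtype=float):
        pars = params_base.with_(b_deg=b)
        for tau1 in np.asarray(tau1_values, dtype=float):
            tau2 = tau_sum - tau1
            if tau2 < 0:
                continue
            spec = StateDependentDelaySpec(tau1=tau1, tau2=tau2, p=p, beta=beta)
            traj = simulate_state_dependent(pars, spec, t_end=t_end, dt=dt)
            feats = _features_or_none(traj)
            if feats is None or not feats.oscillating:
                rows.append((b, tau1, tau2, False, math.nan, math.nan,
                             math.nan, math.nan, False))
                continue
            equal = abs(feats.s_duration - feats.m_duration) <= equal_tol * feats.period
            rows.append((b, tau1, tau2, True, feats.period, feats.amplitude,
                         feats.s_duration, feats.m_duration, bool(equal)))
    return pd.DataFrame(rows, columns=["b_deg", "tau1", "tau2", "oscillating",
                                       "period", "amplitude", "s_duration",
                                       "m_duration", "equal_flag"])
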