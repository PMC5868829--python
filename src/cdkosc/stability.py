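"""Linear stability of the fixed point for discrete and Gamma-distributed delays.

Writing a perturbation of the discrete-delay model around its fixed point as
u' = -A*u - B*u(t - tau), the coefficients are

    A = b_deg * hill(x*)            (instantaneous self-damping)
    B = b_deg * x* * hill'(x*)      (delayed feedback strength)

and the characteristic equation lambda = -A - B*exp(-lambda*tau) admits a
pure-imaginary root iff B > A, at Hopf frequency omega = sqrt(B^2 - A^2) and
critical delay tau_c = arccos(-A/B) / omega.  Below tau_c the steady state
is stable; above it a limit cycle appears.

For the Gamma-distributed delay the same question is answered through the
exactly equivalent (N+1)-dimensional linear chain: the boundary is located
where the largest real part of the chain Jacobian's spectrum crosses zero as
the mean delay tau_avg varies (a = N/tau_avg).  This avoids tracking
branches of the transcendental factor (a/(a+lambda))^N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import FixedPoint, OscillatorParams, fixed_point, hill, hill_slope
from .errors import ConfigError, DomainError

__all__ = [
    "StabilityResult",
    "linearize",
    "critical_delay_discrete",
    "critical_delay_dimensionless",
    "hopf_boundary_distributed",
    "max_growth_rate_distributed",
    "phase_diagram",
]


@dataclass(frozen=True)
class StabilityResult:
    """Fixed point, linearization coefficients and Hopf crossing (if any)."""

    fixed_point: FixedPoint
    A: float
    B: float
    omega_c: float | None
    tau_c: float | None


def linearize(params: OscillatorParams) -> tuple[float, float]:
    """Linearization coefficients (A, B) of the feedback loop at its fixed point.

    Sign convention: a perturbation u obeys u' = -A*u - B*u_lagged.
    """
    if math.isinf(params.m):
        raise DomainError("linearization requires a finite Hill exponent")
    fp = fixed_point(params)
    A = params.b_deg * hill(fp.cdk1_star, params.K, params.m)
    B = params.b_deg * fp.cdk1_star * hill_slope(fp.cdk1_star, params.K, params.m)
    return float(A), float(B)


def critical_delay_discrete(params: OscillatorParams) -> float | None:
    """Critical delay tau_c of the discrete-delay model, or None if the
    steady state is stable for every delay (B <= A, e.g. any m = 1)."""
    A, B = linearize(params)
    if B <= A:
        return None
    omega = math.sqrt(B * B - A * A)
    return math.acos(-A / B) / omega


def stability_summary(params: OscillatorParams) -> StabilityResult:
    """Full stability record for the discrete-delay model."""
    fp = fixed_point(params)
    A, B = linearize(params)
    if B > A:
        omega = math.sqrt(B * B - A * A)
        tau_c = math.acos(-A / B) / omega
    else:
        omega, tau_c = None, None
    return StabilityResult(fixed_point=fp, A=A, B=B, omega_c=omega, tau_c=tau_c)


def critical_delay_dimensionless(c: float, m: float) -> float | None:
    """Dimensionless critical delay b_deg * tau_c as a function of (c, m) only.

    A and B both scale linearly with b_deg, so the product b_deg * tau_c
    depends only on the balance ratio and the Hill exponent; it is evaluated
    with unit rate and threshold.
    """
    if not c > 0:
        raise DomainError("c must be positive")
    params = OscillatorParams(k_s=c, b_deg=1.0, K=1.0, m=m)
    return critical_delay_discrete(params)


def _chain_jacobian(params: OscillatorParams, N: int, tau_avg: float) -> np.ndarray:
    A, B = linearize(params)
    a = N / tau_avg
    J = np.zeros((N + 1, N + 1))
    J[0, 0] = -A
    J[0, N] = -B
    J[1, 0] = a
    for i in range(1, N + 1):
        J[i, i] = -a
        if i >= 2:
            J[i, i - 1] = a
    return J


def max_growth_rate_distributed(params: OscillatorParams, N: int, tau_avg: float) -> float:
    """Largest real part of the chain Jacobian's spectrum at the fixed point."""
    if N < 1:
        raise DomainError("chain length N must be >= 1")
    if tau_avg <= 0:
        raise DomainError("tau_avg must be positive")
    return float(np.max(np.linalg.eigvals(_chain_jacobian(params, N, tau_avg)).real))


def hopf_boundary_distributed(
    params: OscillatorParams,
    N: int,
    tau_range: tuple[float, float] = (1e-2, 200.0),
    n_scan: int = 300,
    xtol: float = 1e-6,
) -> list[float]:
    """Critical mean delays of the Gamma-distributed model for chain length N.

    Scans the largest spectral real part over a log-spaced grid of tau_avg
    and refines every sign change by bisection.  May return zero crossings
    (always stable, e.g. N = 1), one (destabilization) or two
    (destabilization followed by re-stabilization, as for N = 2).
    """
    taus = np.geomspace(tau_range[0], tau_range[1], n_scan)
    vals = np.array([max_growth_rate_distributed(params, N, t) for t in taus])
    crossings = []
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        f = lambda t: max_growth_rate_distributed(params, N, t)
        crossings.append(float(brentq(f, taus[i], taus[i + 1], xtol=xtol)))
    return crossings


# ---------------------------------------------------------------------------
# phase diagrams

_PARAM_AXES = {"k_s", "b_deg", "K", "m"}
_DELAY_AXES = {"tau", "tau_avg", "N", "tau1", "tau2"}
_SPECIAL_AXES = {"c", "ks_over_K"}
MAX_GRID = 200


def _apply_axis(pdict: dict, ddict: dict, name: str, value: float) -> None:
    if name in _PARAM_AXES:
        pdict[name] = int(value) if name == "N" else value
    elif name in _DELAY_AXES:
        ddict[name] = value
    elif name == "c":
        pdict["b_deg"] = pdict["k_s"] / (value * pdict["K"])
    elif name == "ks_over_K":
        pdict["k_s"] = value * pdict["K"]
    else:
        raise ConfigError(f"unsupported axis '{name}'")


def phase_diagram(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    variant: str = "discrete",
    params: OscillatorParams | None = None,
    delay: dict | None = None,
    simulate: bool = False,
    t_end: float = 600.0,
    dt: float | None = None,
) -> pd.DataFrame:
    """Grid classification {oscillating, period, amplitude} over two axes.

    Axis names: c, tau, m, k_s, b_deg, K, ks_over_K (discrete/relay);
    N, tau_avg (distributed); tau1, tau2 (state_dependent).  Classification
    uses linear stability where available (discrete, distributed) and
    simulation plus feature extraction elsewhere; with ``simulate=True``
    oscillating cells of the stability-classified variants are also
    simulated to attach period and amplitude.
    """
    from .discrete import DiscreteDelaySpec, simulate_discrete
    from .distributed import GammaDelaySpec, simulate_distributed
    from .features import extract_features
    from .relay import relay_period
    from .state_dependent import StateDependentDelaySpec, simulate_state_dependent
    from .errors import InsufficientDataError, NoOscillationError

    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if len(vals1) > MAX_GRID or len(vals2) > MAX_GRID:
        raise ConfigError(f"grid axes are limited to {MAX_GRID} points")
    if params is None:
        params = OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0, m=15.0)
    base_p = {"k_s": params.k_s, "b_deg": params.b_deg, "K": params.K, "m": params.m}
    base_d = dict(delay or {})

    known = _PARAM_AXES | _DELAY_AXES | _SPECIAL_AXES
    for nm in (name1, name2):
        if nm not in known:
            raise ConfigError(f"unsupported axis '{nm}'")

    rows = []
    for v1 in vals1:
        for v2 in vals2:
            pdict, ddict = dict(base_p), dict(base_d)
            _apply_axis(pdict, ddict, name1, v1)
            _apply_axis(pdict, ddict, name2, v2)
            period = amplitude = math.nan
            osc = False
            try:
                if variant == "discrete":
                    pars = OscillatorParams(**pdict)
                    tau = float(ddict["tau"])
                    tau_c = critical_delay_discrete(pars)
                    osc = tau_c is not None and tau > tau_c
                    if osc and simulate:
                        step = min(0.01, tau / 25.0)
                        traj = simulate_discrete(pars, DiscreteDelaySpec(tau),
                                                 history=pars.K * 1.5,
                                                 t_end=t_end, dt=dt or step)
                        f = extract_features(traj)
                        period, amplitude = f.period, f.amplitude
                elif variant == "relay":
                    pars = OscillatorParams(**{**pdict, "m": math.inf})
                    tau = float(ddict["tau"])
                    cyc = relay_period(pars.c, pars.b_deg, tau, K=pars.K)
                    osc = tau > 0
                    if osc:
                        period, amplitude = cyc.period, cyc.x_max - cyc.x_min
                elif variant == "distributed":
                    pars = OscillatorParams(**pdict)
                    N = int(ddict["N"])
                    tau_avg = float(ddict["tau_avg"])
                    osc = max_growth_rate_distributed(pars, N, tau_avg) > 0
                    if osc and simulate:
                        traj = simulate_distributed(pars, GammaDelaySpec(N, tau_avg),
                                                    init=pars.K * 1.5, t_end=t_end,
                                                    dt=dt)
                        f = extract_features(traj)
                        period, amplitude = f.period, f.amplitude
                elif variant == "state_dependent":
                    pars = OscillatorParams(**pdict)
                    spec = StateDependentDelaySpec(
                        tau1=float(ddict.get("tau1", 0.0)),
                        tau2=float(ddict.get("tau2", 0.0)),
                        p=float(ddict.get("p", 5.0)),
                        beta=float(ddict.get("beta", 5.0)))
                    traj = simulate_state_dependent(pars, spec, t_end=t_end,
                                                    dt=dt or 0.02)
                    f = extract_features(traj)
                    osc = f.oscillating
                    if osc:
                        period, amplitude = f.period, f.amplitude
                else:
                    raise ConfigError(f"unknown model variant '{variant}'")
            except (NoOscillationError, InsufficientDataError):
                osc = False
            except KeyError as exc:
                raise ConfigError(f"variant '{variant}' needs delay key {exc}") from exc
            rows.append((v1, v2, bool(osc), period, amplitude))
    return pd.DataFrame(rows, columns=[name1, name2, "oscillating", "period",
                                       "amplitude"])
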