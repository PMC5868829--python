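"""JIT-compiled fixed-step integration kernels.

All delay models use the same numerical core: classical 4th-order
Runge-Kutta on a uniform grid, with lagged values read from the stored past
solution by cubic Hermite interpolation (the node derivatives are stored
alongside the states).  A uniform grid makes the lagged lookup a direct
fractional-index computation, which keeps the kernels simple enough to
compile with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def hill_nb(x: float, K: float, m: float) -> float:
    if x <= 0.0:
        return 0.0
    if m == np.inf:
        if x > K:
            return 1.0
        if x < K:
            return 0.0
        return 0.5
    e = m * np.log(x / K)
    if e > 700.0:
        return 1.0
    if e < -700.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-e))


@njit(cache=True)
def _hermite_lookup(x, dx, q, dt, n_last):
    """Value of the stored solution at fractional grid index ``q``.

    Clamps to the constant pre-history below index 0 and extrapolates
    linearly beyond the last computed node ``n_last`` (only reachable when
    the lag is shorter than one step, i.e. the state-dependent model with a
    near-zero delay).
    """
    if q <= 0.0:
        return x[0]
    if q >= n_last:
        return x[n_last] + (q - n_last) * dt * dx[n_last]
    i0 = int(np.floor(q))
    s = q - i0
    h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
    h10 = s * (1.0 - s) ** 2
    h01 = s * s * (3.0 - 2.0 * s)
    h11 = s * s * (s - 1.0)
    return (h00 * x[i0] + h10 * dt * dx[i0]
            + h01 * x[i0 + 1] + h11 * dt * dx[i0 + 1])


@njit(cache=True)
def discrete_dde_rk4(n_pre, n_total, dt, tau, ks, b, K, m, x, dx, apc):
    """Method-of-steps RK4 for x' = ks - b*x*hill(x(t - tau)).

    ``x[0 : n_pre + 1]`` and ``dx[0 : n_pre + 1]`` hold the pre-history
    (grid times -n_pre*dt .. 0); the kernel fills the rest in place and
    writes the delayed APC/C activity hill(x(t - tau)) into ``apc``.
    """
    lag = tau / dt
    for n in range(n_pre, n_total - 1):
        if lag > 0.0:
            xl0 = _hermite_lookup(x, dx, n - lag, dt, n)
            xlh = _hermite_lookup(x, dx, n + 0.5 - lag, dt, n)
            xl1 = _hermite_lookup(x, dx, n + 1.0 - lag, dt, n)
        else:
            xl0 = x[n]
            xlh = x[n]
            xl1 = x[n]
        h0 = hill_nb(xl0, K, m)
        hh = hill_nb(xlh, K, m)
        h1 = hill_nb(xl1, K, m)
        apc[n] = h0
        k1 = ks - b * x[n] * h0
        dx[n] = k1
        if lag > 0.0:
            k2 = ks - b * (x[n] + 0.5 * dt * k1) * hh
            k3 = ks - b * (x[n] + 0.5 * dt * k2) * hh
            k4 = ks - b * (x[n] + dt * k3) * h1
        else:
            x2 = x[n] + 0.5 * dt * k1
            k2 = ks - b * x2 * hill_nb(x2, K, m)
            x3 = x[n] + 0.5 * dt * k2
            k3 = ks - b * x3 * hill_nb(x3, K, m)
            x4 = x[n] + dt * k3
            k4 = ks - b * x4 * hill_nb(x4, K, m)
        x[n + 1] = x[n] + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        if x[n + 1] < 0.0:
            x[n + 1] = 0.0
    nlast = n_total - 1
    if lag > 0.0:
        xl = _hermite_lookup(x, dx, nlast - lag, dt, nlast - 1)
    else:
        xl = x[nlast]
    hl = hill_nb(xl, K, m)
    apc[nlast] = hl
    dx[nlast] = ks - b * x[nlast] * hl


@njit(cache=True)
def sdd_rk4(n_pre, n_total, dt, tau1, tau2, p, thr, beta, ks, b, K, m,
            x, a, dxx, tau_rec):
    """RK4 for the two-variable state-dependent-delay model.

    x' = ks - b*x*a,  a' = beta*(hill(x(t - tau(a))) - a),
    tau(a) = tau1 + (tau2 - tau1) * a^p / (thr^p + a^p).

    The lag is evaluated from the APC/C activity of the current stage and
    the lagged Cdk1 value is read from the stored past by Hermite
    interpolation (linear extrapolation when the lag is below one step).
    """
    thrp = thr ** p
    for n in range(n_pre, n_total - 1):
        # stage 1 at t_n
        aa = min(max(a[n], 0.0), 1.0)
        tau_s = tau1 + (tau2 - tau1) * aa ** p / (thrp + aa ** p)
        tau_rec[n] = tau_s
        fx1 = ks - b * x[n] * a[n]
        dxx[n] = fx1
        xl = _hermite_lookup(x, dxx, n - tau_s / dt, dt, n)
        fa1 = beta * (hill_nb(xl, K, m) - a[n])
        # stage 2 at t_n + dt/2
        xs = x[n] + 0.5 * dt * fx1
        as_ = a[n] + 0.5 * dt * fa1
        aa = min(max(as_, 0.0), 1.0)
        tau_s = tau1 + (tau2 - tau1) * aa ** p / (thrp + aa ** p)
        fx2 = ks - b * xs * as_
        xl = _hermite_lookup(x, dxx, n + 0.5 - tau_s / dt, dt, n)
        fa2 = beta * (hill_nb(xl, K, m) - as_)
        # stage 3 at t_n + dt/2
        xs = x[n] + 0.5 * dt * fx2
        as_ = a[n] + 0.5 * dt * fa2
        aa = min(max(as_, 0.0), 1.0)
        tau_s = tau1 + (tau2 - tau1) * aa ** p / (thrp + aa ** p)
        fx3 = ks - b * xs * as_
        xl = _hermite_lookup(x, dxx, n + 0.5 - tau_s / dt, dt, n)
        fa3 = beta * (hill_nb(xl, K, m) - as_)
        # stage 4 at t_n + dt
        xs = x[n] + dt * fx3
        as_ = a[n] + dt * fa3
        aa = min(max(as_, 0.0), 1.0)
        tau_s = tau1 + (tau2 - tau1) * aa ** p / (thrp + aa ** p)
        fx4 = ks - b * xs * as_
        xl = _hermite_lookup(x, dxx, n + 1.0 - tau_s / dt, dt, n)
        fa4 = beta * (hill_nb(xl, K, m) - as_)

        x[n + 1] = x[n] + dt * (fx1 + 2.0 * fx2 + 2.0 * fx3 + fx4) / 6.0
        a[n + 1] = a[n] + dt * (fa1 + 2.0 * fa2 + 2.0 * fa3 + fa4) / 6.0
        if x[n + 1] < 0.0:
            x[n + 1] = 0.0
        if a[n + 1] < 0.0:
            a[n + 1] = 0.0
        elif a[n + 1] > 1.0:
            a[n + 1] = 1.0
    nlast = n_total - 1
    dxx[nlast] = ks - b * x[nlast] * a[nlast]
    aa = min(max(a[nlast], 0.0), 1.0)
    tau_rec[nlast] = tau1 + (tau2 - tau1) * aa ** p / (thrp + aa ** p)


@njit(cache=True)
def chain_rk4(n_total, dt, ks, b, K, m, arate, s0, x_out, apc_out):
    """RK4 for the linear-chain (Gamma-distributed delay) ODE system.

    State vector: s[0] = Cdk1, s[1..N] = delayed copies;
    s[0]' = ks - b*s[0]*hill(s[N]),  s[i]' = arate*(s[i-1] - s[i]).
    """
    nd = s0.shape[0]
    s = s0.copy()
    k1 = np.empty(nd)
    k2 = np.empty(nd)
    k3 = np.empty(nd)
    k4 = np.empty(nd)
    tmp = np.empty(nd)
    for n in range(n_total):
        x_out[n] = s[0]
        apc_out[n] = hill_nb(s[nd - 1], K, m)
        if n == n_total - 1:
            break
        _chain_deriv(s, ks, b, K, m, arate, k1)
        for i in range(nd):
            tmp[i] = s[i] + 0.5 * dt * k1[i]
        _chain_deriv(tmp, ks, b, K, m, arate, k2)
        for i in range(nd):
            tmp[i] = s[i] + 0.5 * dt * k2[i]
        _chain_deriv(tmp, ks, b, K, m, arate, k3)
        for i in range(nd):
            tmp[i] = s[i] + dt * k3[i]
        _chain_deriv(tmp, ks, b, K, m, arate, k4)
        for i in range(nd):
            s[i] = s[i] + dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0
            if s[i] < 0.0:
                s[i] = 0.0


@njit(cache=True)
def _chain_deriv(s, ks, b, K, m, arate, out):
    nd = s.shape[0]
    out[0] = ks - b * s[0] * hill_nb(s[nd - 1], K, m)
    for i in range(1, nd):
        out[i] = arate * (s[i - 1] - s[i])


@njit(cache=True)
def chain_driven_rk4(n_total, dt, arate, u_lo, u_hi, i_step, y0, y_out):
    """Linear chain driven by a prescribed Cdk1 step input (no feedback).

    Input u = u_lo for node index < i_step, u_hi afterwards (the step is
    aligned to a grid node).  Writes the last chain variable y_N over time.
    """
    nd = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(nd)
    k2 = np.empty(nd)
    k3 = np.empty(nd)
    k4 = np.empty(nd)
    tmp = np.empty(nd)
    for n in range(n_total):
        y_out[n] = y[nd - 1]
        if n == n_total - 1:
            break
        u0 = u_lo if n < i_step else u_hi
        uh = u_lo if (n + 0.5) < i_step else u_hi
        u1 = u_lo if (n + 1) < i_step else u_hi
        _driven_deriv(y, arate, u0, k1)
        for i in range(nd):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _driven_deriv(tmp, arate, uh, k2)
        for i in range(nd):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _driven_deriv(tmp, arate, uh, k3)
        for i in range(nd):
            tmp[i] = y[i] + dt * k3[i]
        _driven_deriv(tmp, arate, u1, k4)
        for i in range(nd):
            y[i] = y[i] + dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0


@njit(cache=True)
def _driven_deriv(y, arate, u, out):
    nd = y.shape[0]
    out[0] = arate * (u - y[0])
    for i in range(1, nd):
        out[i] = arate * (y[i - 1] - y[i])


@njit(cache=True)
def cascade_rk4(n_total, dt, k, gamma, k_back, u_lo, u_hi, i_step, s0, last_out):
    """Multi-step phosphorylation cascade with Cdk1-catalyzed forward steps.

    s holds the fractions in phosphorylation states 0..n; each forward step
    proceeds at rate k*u(t) (the final step scaled by gamma); an optional
    uniform back-rate k_back models dephosphorylation.  Writes the fraction
    in the final (active) state over time.
    """
    nd = s0.shape[0]
    s = s0.copy()
    k1 = np.empty(nd)
    k2 = np.empty(nd)
    k3 = np.empty(nd)
    k4 = np.empty(nd)
    tmp = np.empty(nd)
    for n in range(n_total):
        last_out[n] = s[nd - 1]
        if n == n_total - 1:
            break
        u0 = u_lo if n < i_step else u_hi
        uh = u_lo if (n + 0.5) < i_step else u_hi
        u1 = u_lo if (n + 1) < i_step else u_hi
        _cascade_deriv(s, k, gamma, k_back, u0, k1)
        for i in range(nd):
            tmp[i] = s[i] + 0.5 * dt * k1[i]
        _cascade_deriv(tmp, k, gamma, k_back, uh, k2)
        for i in range(nd):
            tmp[i] = s[i] + 0.5 * dt * k2[i]
        _cascade_deriv(tmp, k, gamma, k_back, uh, k3)
        for i in range(nd):
            tmp[i] = s[i] + dt * k3[i]
        _cascade_deriv(tmp, k, gamma, k_back, u1, k4)
        for i in range(nd):
            s[i] = s[i] + dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0


@njit(cache=True)
def _cascade_deriv(s, k, gamma, k_back, u, out):
    nd = s.shape[0]
    nsteps = nd - 1
    for i in range(nd):
        out[i] = 0.0
    for i in range(nsteps):
        rate = k * u
        if i == nsteps - 1:
            rate *= gamma
        flux = rate * s[i] - k_back * s[i + 1]
        out[i] -= flux
        out[i + 1] += flux
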