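import math

import numpy as np
import pytest

from cdkosc import (
    DiscreteDelaySpec,
    OscillatorParams,
    extract_features,
    fixed_point,
    relay_period,
    relay_period_from_trajectory,
    simulate_discrete,
    simulate_relay,
    step_response_discrete,
)
from cdkosc.errors import DomainError, ResolutionError


class TestSimulateDiscrete:
    def test_equilibrium_is_invariant(self, base_params):
        # starting exactly at the fixed point (with constant history) stays there
        fp = fixed_point(base_params)
        traj = simulate_discrete(base_params, DiscreteDelaySpec(2.0),
                                 history=fp.cdk1_star, t_end=50.0, dt=0.01)
        assert np.max(np.abs(traj.cdk1 - fp.cdk1_star)) < 1e-8

    def test_positivity(self, base_params):
        traj = simulate_discrete(base_params, DiscreteDelaySpec(15.0),
                                 history=80.0, t_end=300.0, dt=0.01)
        assert np.all(traj.cdk1 >= 0.0)
        assert np.all((traj.apc >= 0.0) & (traj.apc <= 1.0))

    def test_self_convergence_under_dt_halving(self, base_params):
        # fixed-step RK4 with Hermite history lookup: halving dt changes the
        # late-time solution by < 0.1%
        kw = dict(history=48.0, t_end=200.0)
        spec = DiscreteDelaySpec(15.0)
        a = simulate_discrete(base_params, spec, dt=0.02, **kw)
        b = simulate_discrete(base_params, spec, dt=0.01, **kw)
        ia = np.searchsorted(a.t, 100.0)
        xa = np.interp(b.t[b.t >= 100.0], a.t[ia:], a.cdk1[ia:])
        xb = b.cdk1[b.t >= 100.0]
        assert np.max(np.abs(xa - xb)) / np.max(xb) < 1e-3

    def test_resolution_guard(self, base_params):
        with pytest.raises(ResolutionError):
            simulate_discrete(base_params, DiscreteDelaySpec(1.0),
                              history=48.0, t_end=10.0, dt=0.5)

    def test_callable_history(self, base_params):
        traj = simulate_discrete(base_params, DiscreteDelaySpec(5.0),
                                 history=lambda t: 48.0 + 0.0 * t,
                                 t_end=100.0, dt=0.01)
        const = simulate_discrete(base_params, DiscreteDelaySpec(5.0),
                                  history=48.0, t_end=100.0, dt=0.01)
        assert np.allclose(traj.cdk1, const.cdk1, atol=1e-9)

    def test_zero_delay_settles(self, base_params):
        # no delay: monotone negative feedback settles to the fixed point
        traj = simulate_discrete(base_params, DiscreteDelaySpec(0.0),
                                 history=48.0, t_end=400.0, dt=0.01)
        fp = fixed_point(base_params)
        assert abs(traj.cdk1[-1] - fp.cdk1_star) < 0.01

    def test_sustained_oscillation_amplitude_grows_with_tau(self, base_params):
        feats = []
        for tau in (6.0, 10.0, 15.0):
            traj = simulate_discrete(base_params, DiscreteDelaySpec(tau),
                                     history=48.0, t_end=400.0, dt=0.01)
            feats.append(extract_features(traj))
        assert all(f.oscillating for f in feats)
        amps = [f.amplitude for f in feats]
        assert amps[0] < amps[1] < amps[2]


class TestRelaySolver:
    def test_matches_high_m_simulation(self, base_params):
        # the event-driven relay and the smooth model at m = 50 agree on the
        # period to better than 1%
        p50 = base_params.with_(m=50.0)
        traj = simulate_discrete(p50, DiscreteDelaySpec(15.0),
                                 history=48.0, t_end=400.0, dt=0.005)
        f = extract_features(traj)
        relay = simulate_relay(base_params.with_(m=math.inf),
                               DiscreteDelaySpec(15.0), x0=48.0, t_end=400.0)
        period = relay_period_from_trajectory(relay)
        assert f.period == pytest.approx(period, rel=0.01)

    def test_period_matches_closed_form(self):
        p = OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0, m=math.inf)
        traj = simulate_relay(p, DiscreteDelaySpec(10.0), x0=40.0, t_end=600.0)
        assert relay_period_from_trajectory(traj) == pytest.approx(
            relay_period(p.c, p.b_deg, 10.0, K=p.K).period, abs=1e-9)

    def test_start_exactly_at_threshold(self):
        p = OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0, m=math.inf)
        traj = simulate_relay(p, DiscreteDelaySpec(8.0), x0=32.0, t_end=400.0)
        assert traj.meta["oscillating"]
        assert traj.events[0] == (0.0, "cross_up")

    def test_non_oscillating_for_c_above_one(self):
        p = OscillatorParams(k_s=2.0, b_deg=0.05, K=32.0, m=math.inf)
        traj = simulate_relay(p, DiscreteDelaySpec(10.0), x0=10.0, t_end=400.0)
        assert not traj.meta["oscillating"]

    def test_events_alternate(self):
        p = OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0, m=math.inf)
        traj = simulate_relay(p, DiscreteDelaySpec(10.0), x0=40.0, t_end=400.0)
        kinds = [k for _, k in traj.events if k.startswith("cross")]
        for a, b in zip(kinds[:-1], kinds[1:]):
            assert a != b


class TestStepResponse:
    def test_delayed_switch(self):
        resp = step_response_discrete(DiscreteDelaySpec(10.0), step_time=0.0,
                                      K=32.0, m=math.inf, step_level=64.0)
        # APC/C output is 0 before the delay has elapsed, 1 after
        assert np.all(resp.value[resp.t < 10.0 - 1e-9] == 0.0)
        assert np.all(resp.value[resp.t > 10.0 + 1e-9] == 1.0)
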