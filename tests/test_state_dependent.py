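import math

import numpy as np
import pytest

from cdkosc import (
    DiscreteDelaySpec,
    OscillatorParams,
    StateDependentDelaySpec,
    extract_features,
    simulate_discrete,
    simulate_state_dependent,
    tau_of_apc,
    zero_delay_boundary,
)
from cdkosc.state_dependent import delay_budget_scan, delay_pair_scan
from cdkosc.errors import DomainError


class TestDelaySwitch:
    def test_endpoints_and_midpoint(self):
        spec = StateDependentDelaySpec(tau1=10.0, tau2=5.0, p=5.0)
        assert tau_of_apc(0.0, spec) == pytest.approx(10.0)
        assert tau_of_apc(1.0, spec) == pytest.approx(5.0, rel=0.05)
        assert tau_of_apc(0.5, spec) == pytest.approx(7.5)  # half-switch

    def test_monotone_between_delays(self):
        spec = StateDependentDelaySpec(tau1=10.0, tau2=5.0, p=5.0)
        a = np.linspace(0.0, 1.0, 101)
        taus = tau_of_apc(a, spec)
        assert np.all(np.diff(taus) <= 1e-12)
        assert np.all((taus <= 10.0 + 1e-12) & (taus >= 5.0 - 1e-2))

    def test_rejects_out_of_range_activity(self):
        spec = StateDependentDelaySpec(tau1=10.0, tau2=5.0)
        with pytest.raises(DomainError):
            tau_of_apc(1.5, spec)

    def test_spec_validation(self):
        with pytest.raises(DomainError):
            StateDependentDelaySpec(tau1=-1.0, tau2=5.0)
        with pytest.raises(DomainError):
            StateDependentDelaySpec(tau1=5.0, tau2=5.0, beta=0.0)


class TestSimulate:
    def test_reduces_to_discrete_model_at_large_beta(self, base_params):
        # tau1 = tau2 = tau, beta = 50: period matches the discrete model within 2%
        tau = 5.0
        spec = StateDependentDelaySpec(tau1=tau, tau2=tau, beta=50.0)
        sd = simulate_state_dependent(base_params, spec, history=(48.0, 0.0),
                                      t_end=400.0, dt=0.01)
        disc = simulate_discrete(base_params, DiscreteDelaySpec(tau),
                                 history=48.0, t_end=400.0, dt=0.01)
        f_sd, f_disc = extract_features(sd), extract_features(disc)
        assert f_sd.oscillating and f_disc.oscillating
        assert f_sd.period == pytest.approx(f_disc.period, rel=0.02)

    def test_reduction_improves_with_beta(self, base_params):
        tau = 5.0
        disc = simulate_discrete(base_params, DiscreteDelaySpec(tau),
                                 history=48.0, t_end=400.0, dt=0.01)
        p_disc = extract_features(disc).period
        errs = []
        for beta in (10.0, 30.0, 90.0):
            spec = StateDependentDelaySpec(tau1=tau, tau2=tau, beta=beta)
            sd = simulate_state_dependent(base_params, spec, history=(48.0, 0.0),
                                          t_end=400.0, dt=0.01)
            errs.append(abs(extract_features(sd).period - p_disc))
        assert errs[0] > errs[-1]

    def test_reference_preset_alternates_delays(self):
        # k_s = 1, b_deg = 0.1, m = 15, p = 5, tau1 = 10, tau2 = 5:
        # sustained oscillation with the lag alternating near 10 and 5
        p = OscillatorParams(k_s=1.0, b_deg=0.1, K=32.0, m=15.0)
        spec = StateDependentDelaySpec(tau1=10.0, tau2=5.0, p=5.0, beta=5.0)
        traj = simulate_state_dependent(p, spec, history=(40.0, 0.0),
                                        t_end=400.0, dt=0.02)
        f = extract_features(traj)
        assert f.oscillating
        late = traj.tau[traj.t > 200.0]
        assert late.max() > 9.0 and late.min() < 6.0

    def test_delay_stays_between_bounds(self):
        p = OscillatorParams(k_s=1.0, b_deg=0.1, K=32.0, m=15.0)
        spec = StateDependentDelaySpec(tau1=10.0, tau2=5.0)
        traj = simulate_state_dependent(p, spec, t_end=200.0, dt=0.02)
        assert np.all(traj.tau <= 10.0 + 1e-9)
        assert np.all(traj.tau >= 5.0 - 1e-9)

    def test_apc_stays_in_unit_interval(self, base_params):
        spec = StateDependentDelaySpec(tau1=8.0, tau2=3.0)
        traj = simulate_state_dependent(base_params, spec, history=(60.0, 0.5),
                                        t_end=300.0, dt=0.02)
        assert np.all((traj.apc >= 0.0) & (traj.apc <= 1.0))

    def test_zero_delays_settle_to_fixed_point(self, base_params):
        from cdkosc import fixed_point
        spec = StateDependentDelaySpec(tau1=0.0, tau2=0.0, beta=20.0)
        traj = simulate_state_dependent(base_params, spec, history=(48.0, 0.0),
                                        t_end=600.0, dt=0.02)
        fp = fixed_point(base_params)
        assert abs(traj.cdk1[-1] - fp.cdk1_star) < 0.05
        f = extract_features(traj)
        assert not f.oscillating


class TestScans:
    def test_pair_scan_equal_diagonal(self, base_params):
        # on the tau1 = tau2 diagonal the S/M balance is set by c alone;
        # scan a small grid and check schema + an oscillating diagonal cell
        df = delay_pair_scan(base_params, [4.0, 8.0], [4.0, 8.0],
                             t_end=300.0, dt=0.02)
        assert set(df.columns) == {"tau1", "tau2", "oscillating", "period",
                                   "amplitude", "s_duration", "m_duration",
                                   "equal_flag"}
        assert len(df) == 4
        cell = df[(df.tau1 == 8.0) & (df.tau2 == 8.0)].iloc[0]
        assert cell.oscillating and np.isfinite(cell.period)

    def test_budget_scan_respects_budget(self, base_params):
        df = delay_budget_scan(base_params, [0.1, 0.2], [3.0, 7.0, 12.0],
                               tau_sum=15.0, t_end=300.0, dt=0.02)
        assert np.allclose(df.tau1 + df.tau2, 15.0)

    def test_zero_delay_boundary_shapes(self):
        p = OscillatorParams(k_s=1.25, b_deg=0.1, K=32.0, m=20.0)
        df = zero_delay_boundary(p, c_values=[0.2, 0.8], tau_values=[6.0],
                                 which="tau2_zero", t_end=300.0)
        assert list(df.columns) == ["c", "tau", "oscillating"]
        assert len(df) == 2
        with pytest.raises(DomainError):
            zero_delay_boundary(p, [0.5], [5.0], which="bogus")
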