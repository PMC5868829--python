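import math

import numpy as np
import pytest

from cdkosc import (
    DiscreteDelaySpec,
    OscillatorParams,
    critical_delay_dimensionless,
    critical_delay_discrete,
    extract_features,
    hill,
    hill_slope,
    hopf_boundary_distributed,
    linearize,
    max_growth_rate_distributed,
    phase_diagram,
    simulate_discrete,
    stability_summary,
)
from cdkosc.errors import ConfigError, DomainError


class TestLinearization:
    def test_frozen_reference_point(self, base_params):
        # k_s=1.28, b_deg=0.1, K=32, m=15 (frozen)
        s = stability_summary(base_params)
        assert s.fixed_point.cdk1_star == pytest.approx(31.23152720529856, abs=1e-9)
        assert s.A == pytest.approx(0.04098422698275361, abs=1e-12)
        assert s.B == pytest.approx(0.36280737553522374, abs=1e-12)
        assert s.omega_c == pytest.approx(0.3604850688744029, abs=1e-10)
        assert s.tau_c == pytest.approx(4.671489243128855, abs=1e-9)

    def test_coefficients_match_definitions(self, base_params):
        from cdkosc import fixed_point
        A, B = linearize(base_params)
        fp = fixed_point(base_params)
        assert A == pytest.approx(
            base_params.b_deg * hill(fp.cdk1_star, base_params.K, base_params.m))
        assert B == pytest.approx(
            base_params.b_deg * fp.cdk1_star
            * hill_slope(fp.cdk1_star, base_params.K, base_params.m))

    def test_b_over_a_closed_form(self, base_params):
        # B/A = m / (1 + (x*/K)^m), a consequence of the Hill shape
        from cdkosc import fixed_point
        A, B = linearize(base_params)
        x = fixed_point(base_params).cdk1_star
        m, K = base_params.m, base_params.K
        assert B / A == pytest.approx(m / (1 + (x / K) ** m), rel=1e-10)

    def test_a_equals_half_b_deg_at_c_half(self):
        # at c = 1/2 the fixed point sits exactly at apc* = 1/2
        p = OscillatorParams(k_s=0.5 * 0.08 * 32.0, b_deg=0.08, K=32.0, m=15.0)
        A, _ = linearize(p)
        assert A == pytest.approx(p.b_deg / 2.0, rel=1e-9)

    def test_requires_finite_m(self):
        with pytest.raises(DomainError):
            linearize(OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0, m=math.inf))


class TestCriticalDelayDiscrete:
    def test_m_one_is_always_stable(self):
        p = OscillatorParams(k_s=1.28, b_deg=0.1, K=32.0, m=1.0)
        assert critical_delay_discrete(p) is None
        s = stability_summary(p)
        assert s.tau_c is None and s.omega_c is None

    def test_simulation_brackets_the_boundary(self, base_params):
        # decay just below tau_c, sustained growth just above: the slope of
        # log(peak deviation) changes sign across the computed boundary
        tau_c = critical_delay_discrete(base_params)
        from cdkosc import fixed_point
        xstar = fixed_point(base_params).cdk1_star

        def envelope_slope(tau: float) -> float:
            traj = simulate_discrete(base_params, DiscreteDelaySpec(tau),
                                     history=xstar * 1.02, t_end=600.0, dt=0.01)
            dev = np.abs(traj.cdk1 - xstar)
            half = len(dev) // 2
            early = float(np.max(dev[:half]))
            late = float(np.max(dev[half:]))
            return math.log(late / early)

        assert envelope_slope(0.9 * tau_c) < 0
        assert envelope_slope(1.1 * tau_c) > 0

    def test_dimensionless_minimum_near_half(self):
        # b_deg * tau_c over c at m = 15 is minimized near c = 0.5
        cs = np.linspace(0.02, 0.98, 50)
        vals = np.array([critical_delay_dimensionless(c, 15.0) for c in cs],
                        dtype=float)
        c_min = cs[int(np.nanargmin(vals))]
        assert abs(c_min - 0.5) < 0.1
        assert np.nanmin(vals) == pytest.approx(0.45768835352948656, rel=1e-9)

    def test_dimensionless_is_scale_free(self):
        # the product b_deg * tau_c must not depend on b_deg or K separately
        c, m = 0.4, 15.0
        ref = critical_delay_dimensionless(c, m)
        for b, K in ((0.05, 32.0), (0.3, 32.0), (0.1, 100.0)):
            p = OscillatorParams(k_s=c * b * K, b_deg=b, K=K, m=m)
            assert b * critical_delay_discrete(p) == pytest.approx(ref, rel=1e-9)


class TestDistributedBoundary:
    def test_n1_never_oscillates_in_parameter_box(self, table_box):
        # exponential kernel: stable for every mean delay across the box
        for k_s in np.linspace(*table_box["k_s"], 3):
            for b in np.linspace(*table_box["b_deg"], 4):
                p = OscillatorParams(k_s=k_s, b_deg=b, K=table_box["K"], m=20.0)
                assert hopf_boundary_distributed(p, 1) == []

    def test_n2_two_crossings(self, base_params):
        # N = 2 destabilizes and then re-stabilizes: exactly two crossings
        crossings = hopf_boundary_distributed(base_params, 2)
        assert len(crossings) == 2
        lo, hi = crossings
        assert max_growth_rate_distributed(base_params, 2, 0.5 * lo) < 0
        assert max_growth_rate_distributed(base_params, 2, 0.5 * (lo + hi)) > 0
        assert max_growth_rate_distributed(base_params, 2, 2.0 * hi) < 0

    def test_boundary_converges_monotonically_to_discrete(self, base_params):
        tau_c = critical_delay_discrete(base_params)
        firsts = [hopf_boundary_distributed(base_params, N)[0]
                  for N in (2, 5, 10, 50, 200)]
        assert all(a > b for a, b in zip(firsts[:-1], firsts[1:]))
        assert all(f > tau_c for f in firsts)
        assert firsts[-1] == pytest.approx(tau_c, rel=0.01)

    def test_frozen_first_crossings(self, base_params):
        assert hopf_boundary_distributed(base_params, 5)[0] == pytest.approx(
            6.785922401338674, abs=1e-4)
        assert hopf_boundary_distributed(base_params, 50)[0] == pytest.approx(
            4.81944981871866, abs=1e-4)

    def test_growth_rate_input_validation(self, base_params):
        with pytest.raises(DomainError):
            max_growth_rate_distributed(base_params, 0, 5.0)
        with pytest.raises(DomainError):
            max_growth_rate_distributed(base_params, 4, -1.0)


class TestPhaseDiagram:
    def test_discrete_tau_axis_matches_tau_c(self, base_params):
        tau_c = critical_delay_discrete(base_params)
        df = phase_diagram(("tau", np.linspace(1.0, 10.0, 10)),
                           ("m", np.array([15.0])),
                           variant="discrete", params=base_params)
        for _, row in df.iterrows():
            assert row.oscillating == (row.tau > tau_c)

    def test_relay_grid_has_periods(self):
        p = OscillatorParams(k_s=1.25, b_deg=0.08, K=32.0)
        df = phase_diagram(("b_deg", np.linspace(0.05, 0.4, 5)),
                           ("tau", np.linspace(1.0, 15.0, 5)),
                           variant="relay", params=p)
        osc = df[df.oscillating]
        assert len(osc) > 0 and np.all(np.isfinite(osc.period))

    def test_unknown_axis_rejected(self, base_params):
        with pytest.raises(ConfigError):
            phase_diagram(("bogus", np.array([1.0])), ("tau", np.array([5.0])),
                          variant="discrete", params=base_params)

    def test_grid_size_limit(self, base_params):
        with pytest.raises(ConfigError):
            phase_diagram(("tau", np.linspace(1, 10, 500)),
                          ("m", np.array([15.0])),
                          variant="discrete", params=base_params)
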