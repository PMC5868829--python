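"""Named parameter presets for reference scenarios.

Trajectory presets feed ``cdkosc simulate``; scan presets feed
``cdkosc scan``.  Each preset pins every kinetic and delay parameter of one
reference scenario; where a scenario underdetermines a value (the m and tau
of the two discrete-delay time series, the beta of the state-dependent
example) a representative choice is filled in and noted in the methods
documentation.
"""

from __future__ import annotations

TRAJECTORY_PRESETS: dict[str, dict] = {
    # discrete delay, small-amplitude sinusoidal oscillation near the boundary
    "fig2g": {
        "model": "discrete",
        "params": {"k_s": 1.28, "b_deg": 0.1, "K": 32.0, "m": 15.0},
        "delay": {"tau": 3.0},
        "sim": {"t_end": 400.0, "dt": 0.01, "x0": 48.0},
    },
    # discrete delay, relaxation-like sawtooth far from the boundary
    "fig2h": {
        "model": "discrete",
        "params": {"k_s": 1.28, "b_deg": 0.1, "K": 32.0, "m": 15.0},
        "delay": {"tau": 15.0},
        "sim": {"t_end": 400.0, "dt": 0.01, "x0": 48.0},
    },
    # state-dependent delay alternating between tau1 = 10 and tau2 = 5
    "fig5b": {
        "model": "state_dependent",
        "params": {"k_s": 1.0, "b_deg": 0.1, "K": 32.0, "m": 15.0},
        "delay": {"tau1": 10.0, "tau2": 5.0, "p": 5.0, "beta": 5.0},
        "sim": {"t_end": 400.0, "dt": 0.02, "x0": 40.0, "apc0": 0.0},
    },
}

SCAN_PRESETS: dict[str, dict] = {
    # discrete-delay (m, tau) phase diagram with period in color
    "fig2e": {
        "model": "discrete",
        "params": {"k_s": 1.28, "b_deg": 0.1, "K": 32.0, "m": 15.0},
        "axes": [
            {"name": "m", "start": 2.0, "stop": 30.0, "num": 15},
            {"name": "tau", "start": 1.0, "stop": 20.0, "num": 15},
        ],
        "simulate": True,
    },
    # relay period over (b_deg, tau) with the realistic-period band
    "fig3e": {
        "model": "relay",
        "params": {"k_s": 1.25, "b_deg": 0.08, "K": 32.0},
        "axes": [
            {"name": "b_deg", "start": 0.04, "stop": 0.4, "num": 37},
            {"name": "tau", "start": 0.0, "stop": 20.0, "num": 41},
        ],
    },
    # state-dependent (tau1, tau2) period map, low c
    "fig5d": {
        "model": "state_dependent",
        "params": {"k_s": 1.2, "b_deg": 0.125, "K": 32.0, "m": 20.0},
        "delay": {"p": 5.0, "beta": 5.0},
        "axes": [
            {"name": "tau1", "start": 0.0, "stop": 15.0, "num": 15},
            {"name": "tau2", "start": 0.0, "stop": 15.0, "num": 15},
        ],
    },
    # state-dependent (tau1, tau2) period map, high c
    "fig5e": {
        "model": "state_dependent",
        "params": {"k_s": 1.0, "b_deg": 0.0625, "K": 32.0, "m": 20.0},
        "delay": {"p": 5.0, "beta": 5.0},
        "axes": [
            {"name": "tau1", "start": 0.0, "stop": 15.0, "num": 15},
            {"name": "tau2", "start": 0.0, "stop": 15.0, "num": 15},
        ],
    },
    # state-dependent (b_deg, tau1) map with tau1 + tau2 = 15 min
    "fig5f": {
        "model": "state_dependent_budget",
        "params": {"k_s": 1.25, "b_deg": 0.1, "K": 32.0, "m": 20.0},
        "delay": {"p": 5.0, "beta": 5.0, "tau_sum": 15.0},
        "axes": [
            {"name": "b_deg", "start": 0.04, "stop": 0.4, "num": 25},
            {"name": "tau1", "start": 0.0, "stop": 15.0, "num": 16},
        ],
    },
}
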