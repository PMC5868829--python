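import numpy as np
import pytest

from cdkosc import OscillatorParams


@pytest.fixture(scope="session")
def base_params() -> OscillatorParams:
    """Representative oscillating parameter point (c = 0.4, m = 15)."""
    return OscillatorParams(k_s=1.28, b_deg=0.1, K=32.0, m=15.0)


@pytest.fixture(scope="session")
def table_box() -> dict:
    """The model study's physiological parameter ranges."""
    return {
        "k_s": (1.0, 1.5),
        "b_deg": (0.04, 0.4),
        "K": 32.0,
        "tau": (5.0, 40.0),
        "m_min": 15.0,
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20180101)
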