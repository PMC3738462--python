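import numpy as np
import pytest

from homeofront import CircuitParams, StimulusProtocol


@pytest.fixture
def protocol():
    """Default square-pulse protocol used across the unit tests."""
    return StimulusProtocol(I0=1.0, I1=3.0, t_amb=5.0, t_step=1.0)


@pytest.fixture
def params():
    return CircuitParams(k=2.0, y0=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_setup(rng, k_range=(0.2, 30.0)):
    """One random (params, protocol) pair with a well-conditioned step."""
    k = float(np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]))))
    y0 = float(rng.uniform(0.05, 2.0))
    I0 = float(rng.uniform(0.5, 2.0))
    I1 = I0 + float(rng.uniform(0.1, 3.0))
    t_amb = float(rng.uniform(0.5, 8.0))
    return CircuitParams(k=k, y0=y0), StimulusProtocol(
        I0=I0, I1=I1, t_amb=t_amb, t_step=1.0)
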