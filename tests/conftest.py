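import numpy as np
import pytest

from ceasl import AcquisitionParams, PhysioParams


@pytest.fixture
def phys():
    """Simulation operating point: f=60, t_A=1.2 s, k_b=2.65 s^-1."""
    return PhysioParams()


@pytest.fixture
def acq():
    return AcquisitionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_phys(rng, t1_b=None):
    """Random parameter draw covering the simulation ranges."""
    return PhysioParams(
        f=rng.uniform(20, 100),
        t_A=rng.uniform(0.5, 2.0),
        k_b=rng.uniform(0.0, 5.0),
        T1_b=t1_b if t1_b is not None else rng.uniform(0.15, 1.65),
        T1_e=rng.uniform(0.8, 1.8),
        lambda_=0.9,
    )
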