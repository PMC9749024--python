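import numpy as np
import pytest

from bpmdkit import (AlignedRmsdCV, ProtocolConfig, SyntheticSpec,
                     make_toy_complex)


@pytest.fixture
def spec():
    return SyntheticSpec(seed=42)


@pytest.fixture
def fixture(spec):
    """Toy complex with the bound pose plus 2.5 and 6.0 Å displaced poses."""
    return make_toy_complex(spec, pose_rmsds_A=(2.5, 6.0))


@pytest.fixture
def complex_(fixture):
    return fixture.complex


@pytest.fixture
def cv(complex_):
    return AlignedRmsdCV.from_complex(complex_)


@pytest.fixture
def short_config():
    """Desk-scale protocol: 1 ns runs, 0.5 ns tail, 3 replicas."""
    return ProtocolConfig(duration_ns=1.0, tail_ns=0.5, n_replicas=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_perturbed_frame(rng, complex_, scale=0.3):
    """Reference coordinates plus small Gaussian noise on every atom."""
    return complex_.coords + rng.normal(0.0, scale, (complex_.n_atoms, 3))
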