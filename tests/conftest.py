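import numpy as np
import pytest

from nrlangevin import (DimerParams, constant_J_drift, make_gaussian,
                        make_periodic, make_warped_gaussian)

ROT2 = np.array([[0.0, -1.0], [1.0, 0.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20160322)


@pytest.fixture
def gaussian2d():
    return make_gaussian(2)


@pytest.fixture
def warped():
    return make_warped_gaussian(0.05)


@pytest.fixture
def periodic():
    return make_periodic(10.0)


@pytest.fixture
def rotation_field(gaussian2d):
    """The planar rotation γ(x) = (x₂, −x₁) on the standard 2-D Gaussian."""
    return constant_J_drift(ROT2, gaussian2d)


@pytest.fixture
def dimer_params():
    return DimerParams(n_particles=8, box_length=4.0)
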