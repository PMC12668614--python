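import numpy as np
import pytest

from planktosink import (
    ComponentDensities,
    FluidEnvironment,
    MolecularComposition,
)
from planktosink.synth import representative_composition


@pytest.fixture
def densities():
    return ComponentDensities()


@pytest.fixture
def seawater():
    return FluidEnvironment()


@pytest.fixture
def half_water_protein():
    return MolecularComposition(water=50.0, protein=50.0)


@pytest.fixture
def representative():
    return representative_composition()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def central_difference(f, x, rel_step=1e-6):
    """Independent derivative oracle: central finite difference at x."""
    h = rel_step * max(abs(x), 1.0)
    return (f(x + h) - f(x - h)) / (2.0 * h)
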