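import numpy as np
import pytest

from shellpick.synthetic import alanine_water_spec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_fixture():
    """400-frame stock solvated-alanine fixture with ground-truth labels."""
    spec = alanine_water_spec(400, seed=11)
    traj, labels, names = generate(spec)
    return spec, traj, labels, names


@pytest.fixture(scope="session")
def medium_fixture():
    """8000-frame fixture for basin statistics at moderate cost."""
    spec = alanine_water_spec(8000, seed=7)
    traj, labels, names = generate(spec)
    return spec, traj, labels, names
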