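import numpy as np
import pytest

from psicascade import EnzymeSpec, get_preset


@pytest.fixture(scope="session")
def wt_preset():
    return get_preset("WT_PPNN")


@pytest.fixture(scope="session")
def ry_preset():
    return get_preset("RY")


@pytest.fixture(scope="session")
def yein_preset():
    return get_preset("YEIN_DEFAULT")


@pytest.fixture
def ry_enzyme():
    return EnzymeSpec("RY", 51440.0, mass_conc=2.0)


@pytest.fixture
def t_grid_120():
    return np.linspace(0.0, 120.0, 25)
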