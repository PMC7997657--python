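import numpy as np
import pytest

from switchquant import pmf, synth


@pytest.fixture(scope="session")
def thermo():
    return pmf.Thermo()  # 310 K


@pytest.fixture(scope="session")
def grid13():
    return pmf.make_grid(3.75, 10.25, 13)


@pytest.fixture(scope="session")
def well():
    """Double-well ground truth: 3 kcal/mol barrier, minima at 5 and 9 A."""
    return synth.double_well()


@pytest.fixture(scope="session")
def window_ladder():
    """13 umbrella centers, 4-10 A, spring constant 20 kcal/mol/A^2."""
    return [(float(c), 20.0) for c in np.linspace(4.0, 10.0, 13)]
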