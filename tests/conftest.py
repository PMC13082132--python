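import numpy as np
import pytest

from srpscat import synthetic_data as sd


@pytest.fixture(scope="session")
def species_library():
    return sd.default_species_library()


@pytest.fixture()
def ch_axis():
    """C-H stretching window axis, 5 cm^-1 steps."""
    return np.arange(2800.0, 3101.0, 5.0)


@pytest.fixture()
def amide_axis():
    """Amide-I window axis, 1 cm^-1 steps."""
    return np.arange(1580.0, 1721.0, 1.0)
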