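import numpy as np
import pytest

from tiltps import OpticsParams, build_lut

#: acquisition conditions used throughout: 300 kV, Cs 2.7 mm, 1.22 Å/px
PIXEL_SIZE_A = 1.22


@pytest.fixture(scope="session")
def optics():
    return OpticsParams(pixel_size_a=PIXEL_SIZE_A)


@pytest.fixture(scope="session")
def optics_no_cs():
    """Spherical-aberration-free optics: the stretch factor has a closed form."""
    return OpticsParams(cs_mm=0.0, amplitude_contrast=0.0,
                        pixel_size_a=PIXEL_SIZE_A)


@pytest.fixture(scope="session")
def default_lut(optics):
    """The shipped default LUT (1-7 um, 0.5 um steps); built once per session."""
    return build_lut(optics)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_915)
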