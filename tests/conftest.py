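import dataclasses

import pytest

from protonrbe.models import TABLE1_TISSUES
from protonrbe.sobp import SOBPSpec, generate_sobp_grid


@pytest.fixture(scope="session")
def ab2():
    """Late-responding tissue, (alpha/beta)_x = 2 Gy, D_t = 10 Gy."""
    return dataclasses.replace(TABLE1_TISSUES["ab2"], d_t=10.0)


@pytest.fixture(scope="session")
def ab10():
    """Early-responding tissue / tumour, (alpha/beta)_x = 10 Gy, D_t = 10 Gy."""
    return dataclasses.replace(TABLE1_TISSUES["ab10"], d_t=10.0)


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down SOBP for fast unit tests (same physics, smaller box)."""
    return SOBPSpec(box_lateral_mm=(40.0, 30.0), box_depth_extent_mm=20.0,
                    box_centre_depth_mm=40.0, n_peaks=10,
                    lateral_margin_mm=15.0, depth_margin_mm=15.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_sobp_grid(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The full study phantom: 150 x 90 x 40 mm box centred at 76 mm depth."""
    return generate_sobp_grid()
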