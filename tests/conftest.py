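import numpy as np
import pytest

from cmatsim import AberrationField, FOVSpec, HexTilingSpec, PupilSpec, build_correction_grid


@pytest.fixture(scope="session")
def reference_grid():
    """Reference honeycomb grid: side 577 µm, inclusion radius 3950 µm."""
    return build_correction_grid(FOVSpec(), HexTilingSpec())


@pytest.fixture(scope="session")
def small_pupil():
    """Desk-scale pupil for PSF computations."""
    return PupilSpec(grid_size=64, pad_factor=8)


@pytest.fixture(scope="session")
def radial_field():
    """Default radially growing truth aberration field."""
    return AberrationField(n_terms=11, seed=1)
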