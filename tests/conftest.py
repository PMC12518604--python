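import numpy as np
import pytest

from mfism import Grid, LensDesignSpec


@pytest.fixture
def small_grid() -> Grid:
    return Grid(n=64, step=0.2)


@pytest.fixture
def single_lens_spec() -> LensDesignSpec:
    return LensDesignSpec(wavelength_nm=488.0, numerical_aperture=0.7,
                          diameter_um=100.0, foci_per_side=1, pitch_um=3.0,
                          method="phase_addition")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
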