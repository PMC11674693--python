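import numpy as np
import pytest

from stripscan import StripParams, ahmo, quantise


#: 4x4 toy level grid whose d=1 horizontal pair counts are known by hand.
TOY_GRID = np.array(
    [[0, 0, 1, 1],
     [0, 0, 1, 1],
     [0, 2, 2, 2],
     [2, 2, 3, 3]]
)

#: Hand-counted ordered pair counts for TOY_GRID at d=1 (total 12).
TOY_COUNTS = {
    (0, 0): 2, (0, 1): 2, (1, 1): 2, (0, 2): 1, (2, 2): 3, (2, 3): 1, (3, 3): 1,
}


@pytest.fixture
def toy_grid():
    return TOY_GRID.copy()


@pytest.fixture
def toy_glcm_p():
    """Normalised d=1 GLCM of the toy grid (sums to 1 over 12 pairs)."""
    q = quantise(TOY_GRID.astype(float) * 85, Ng=4, range_mode="per_image")
    assert np.array_equal(q.levels, TOY_GRID)
    return ahmo(q, d_max=1).p


@pytest.fixture
def quiet_params():
    """Noise-free strip parameters: flat background, no speckle, no jitter."""
    return StripParams(
        background_grain_sd=0.0,
        illumination_gradient_amplitude=0.0,
        brightness_jitter_sd=0.0,
        texture_roughness=0.0,
    )
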