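import numpy as np
import pytest

from turingforge.fields import Grid1D, Grid2D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid1d_small():
    return Grid1D(65, 10.0)


@pytest.fixture
def grid2d_small():
    return Grid2D(33, 33, 10.0, 10.0)


@pytest.fixture
def three_tone_image():
    """Nested rectangles at intensities 255 (background), 128, 0."""
    from turingforge.fields import make_fixture_image

    return make_fixture_image(
        (60, 80),
        [
            {"kind": "rect", "row0": 10, "row1": 50, "col0": 15, "col1": 65,
             "intensity": 128},
            {"kind": "rect", "row0": 20, "row1": 40, "col0": 30, "col1": 50,
             "intensity": 0},
        ],
    )
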