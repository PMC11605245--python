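import numpy as np
import pytest

from qdf.core import QuadrantStack
from qdf.phantom import bead_scene, render_quadrants


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_stack(rng):
    """Seeded random 16x16 quadrant stack of 12-bit-ish counts."""
    ims = rng.integers(0, 4096, size=(4, 16, 16))
    return QuadrantStack(*ims, bit_depth=12)


@pytest.fixture(scope="session")
def clean_bead():
    """Noiseless fully directional bead phantom and its ground truth."""
    scene = bead_scene(noise_sigma=0.0, background_level=0.0)
    stack, truth = render_quadrants(scene)
    return scene, stack, truth
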