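import numpy as np
import pytest

from monolayer_mechanics import synthetic as syn
from monolayer_mechanics.fields import GridSpec


@pytest.fixture(scope="session")
def bead_image():
    """Clean bead image for PIV tests (dense, no noise)."""
    return syn.make_bead_image(256, 256, 900, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def scene():
    """Full expanding-front scene at default (study) conditions."""
    return syn.make_expanding_front_scenario(n_frames=3, seed=1)


SMALL_SCENE_KW = dict(
    image_px=320,
    grid_nodes=16,
    front_start=300.0,
    x_back=80.0,
    n_beads=1500,
    n_frames=3,
)


@pytest.fixture(scope="session")
def small_scene():
    """Reduced-geometry scene for fast smoke tests."""
    return syn.make_expanding_front_scenario(seed=3, **SMALL_SCENE_KW)


@pytest.fixture
def grid46():
    return GridSpec(origin=(0.0, 0.0), n_x=46, n_y=46, spacing=20.72)


def relative_l2(au, av, bu, bv):
    return float(np.sqrt(((au - bu) ** 2 + (av - bv) ** 2).sum() / (bu**2 + bv**2).sum()))
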