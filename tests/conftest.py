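"""Shared fixtures: small seeded phantoms and crop specs."""

import numpy as np
import pytest

from esdm.phantom import PhantomConfig, generate_phantom
from esdm.preprocess import CropSpec


@pytest.fixture(scope="session")
def small_phantom():
    """64 x 64, 4 frames x 4 repetitions, seeded; shared read-only."""
    cfg = PhantomConfig(width=64, depth=64, n_frames=4, n_repetitions=4,
                        surface_depth_mean=12, epithelium_thickness_mean=14,
                        boundary_amplitude=3, boundary_smoothness=10, seed=7)
    vol, masks = generate_phantom(cfg)
    return cfg, vol, masks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spec64():
    return CropSpec(64, 64, (0,))
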