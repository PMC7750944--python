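import numpy as np
import pytest
from hypothesis import settings

import beadspot as bs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 32x32 scene with the default bead density."""
    cfg = bs.SceneConfig(rng_seed=7)
    image, ann = bs.generate_scene(cfg)
    return cfg, image, ann


@pytest.fixture(scope="session")
def easy_samples():
    """Ten bright, noise-free, well-separated-bead scenes for quick
    training smoke tests: (image, visible centroids) pairs."""
    out = []
    for i in range(10):
        cfg = bs.SceneConfig(
            n_beads=8,
            touching_fraction=0.0,
            amplitude_range=(0.7, 0.9),
            noise_sigma=0.0,
            rng_seed=100 + i,
        )
        image, ann = bs.generate_scene(cfg)
        out.append((image, ann.visible_centroids()))
    return out
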