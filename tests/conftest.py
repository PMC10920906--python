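import numpy as np
import pytest
from hypothesis import settings

from repeatmeth import synthgen

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """A quick 5-nucleus scene used by several image tests."""
    cfg = synthgen.SceneConfig(seed=42, n_nuclei=5)
    stack, truth = synthgen.simulate_nuclei_stack(cfg, "none")
    return cfg, stack, truth


def disc_image(shape, discs, fg=100.0, bg=0.0):
    """Rasterize discs ((cy, cx, r), ...) onto a flat background."""
    img = np.full(shape, float(bg))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx, r in discs:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = fg
    return img


@pytest.fixture
def disc_factory():
    return disc_image
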