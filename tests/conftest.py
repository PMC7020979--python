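import numpy as np
import pytest

from dirprop.phantom import PhantomConfig, make_planning_phantom
from dirprop.registration import FFDOptions, LevelSpec

# two-level pyramid: enough to verify behaviour at a fraction of the cost
FAST_FFD = FFDOptions(levels=(LevelSpec(4, 32.0, 60), LevelSpec(2, 16.0, 50)))


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=3)


@pytest.fixture(scope="session")
def planning(default_config):
    """Session-wide planning phantom (64x64x40 at 2x2x3 mm)."""
    return make_planning_phantom(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_blob_mask(shape, rng, n_seeds=3, iters=4) -> np.ndarray:
    """Random connected-ish blob for surface/metric oracle tests."""
    from scipy import ndimage

    m = np.zeros(shape, dtype=bool)
    seeds = rng.integers(0, np.asarray(shape), size=(n_seeds, 3))
    for s in seeds:
        m[tuple(s)] = True
    for _ in range(iters):
        m = ndimage.binary_dilation(m)
        m &= rng.random(shape) < 0.9
    m = ndimage.binary_closing(m)
    if not m.any():
        m[tuple(np.asarray(shape) // 2)] = True
    return m
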