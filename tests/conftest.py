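import numpy as np
import pytest
from hypothesis import settings

from vesscade.synth import TreeSpec, make_phantom
from vesscade.volume import Volume

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def straight_tube(shape=(40, 40, 40), radius=2.0, sigma_ratio=0.5,
                  peak=100.0, axis=2, spacing=(1.0, 1.0, 1.0)):
    """Analytic straight tube along a grid axis with a Gaussian profile."""
    coords = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                         indexing="ij")
    center = [(s - 1) * sp / 2.0 for s, sp in zip(shape, spacing)]
    inplane = [i for i in range(3) if i != axis]
    d2 = sum((coords[i] - center[i]) ** 2 for i in inplane)
    sigma = sigma_ratio * radius
    img = peak * np.exp(-d2 / (2.0 * sigma * sigma))
    mask = (d2 <= radius * radius).astype(np.uint8)
    return Volume(img.astype(np.float32), spacing), Volume(mask, spacing)


@pytest.fixture(scope="session")
def tube_volume():
    vol, _ = straight_tube()
    return vol


@pytest.fixture(scope="session")
def tube_mask():
    _, mask = straight_tube()
    return mask


@pytest.fixture(scope="session")
def small_phantom():
    """A depth-2 bifurcating tree in a 64-voxel cube (session-cached)."""
    spec = TreeSpec(shape=(64, 64, 64), depth=2, segment_length=(18.0, 26.0),
                    seed=7)
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
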