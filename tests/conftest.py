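import numpy as np
import pytest

from tumortex.preprocess import QuantizedVOI, quantize


def random_voi(rng, shape=(5, 5, 5), n_levels=4, p_mask=0.7) -> QuantizedVOI:
    """Random small quantized VOI with a random (nonempty) mask."""
    vol = rng.random(shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return quantize(vol, mask, n_levels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_voi(rng):
    return random_voi(rng)


def line_voi(levels_1d, axis=1):
    """A 1-voxel-thick VOI whose levels run along one axis (already quantized values)."""
    levels_1d = np.asarray(levels_1d, dtype=int)
    shape = [1, 1, 1]
    shape[axis] = len(levels_1d)
    lev = levels_1d.reshape(shape)
    mask = np.ones(shape, dtype=bool)
    return QuantizedVOI(levels=lev, mask=mask, n_levels=int(levels_1d.max()))
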