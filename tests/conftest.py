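import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from msglcm.glcm import quantize


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_quantized_volume(rng, shape=(10, 10, 8), Ng=6, mask_density=0.85):
    """Random masked quantized volume; mask always nonempty."""
    raw = rng.random(shape) * 100.0
    mask = rng.random(shape) < mask_density
    mask.flat[0] = True
    return quantize(raw, mask, Ng)


@pytest.fixture
def small_volume(rng):
    return random_quantized_volume(rng)


@pytest.fixture
def random_prob_matrix(rng):
    def make(Ng=6):
        m = rng.random((Ng, Ng)) ** 2
        return m / m.sum()

    return make
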