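import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ohscc.core import ImageVolume, VoiMask
from ohscc.synthetic import LesionSpec, generate_pet_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def constant_phantom():
    """Constant-SUV spherical lesion (SUV 4) in background 1, 2 mm voxels."""
    spec = LesionSpec(center=(16, 16, 16), radius_mm=10.0, background_suv=1.0,
                      lesion_suv_mean=4.0, heterogeneity_texture="constant", seed=3)
    return generate_pet_phantom(spec, shape=(32, 32, 32), spacing_mm=(2.0, 2.0, 2.0))


def random_label_volume(rng, max_side=6, bins=4):
    """A random small label volume + mask for oracle-equivalence checks."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    labels = rng.integers(1, bins + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    return labels, mask
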