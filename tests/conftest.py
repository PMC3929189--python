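import numpy as np
import pytest

from wbckit import SyntheticSceneSpec, default_scene_region, generate_scene
from wbckit.segmentation import BinaryMask


@pytest.fixture(scope="session")
def tone_region():
    return default_scene_region()


@pytest.fixture(scope="session")
def clean_scene():
    """One cell, clean tones, light speckle: the nominal study condition."""
    return generate_scene(SyntheticSceneSpec(seed=3))


@pytest.fixture(scope="session")
def segmented_cell(clean_scene, tone_region):
    from wbckit import segment_cell
    mask, crop = segment_cell(clean_scene.image, tone_region)
    return clean_scene, mask


def disk_mask(radius, pad=2):
    """Digital disk: lattice points with x^2 + y^2 <= r^2."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n] - (radius + pad)
    return BinaryMask(xx ** 2 + yy ** 2 <= radius ** 2)


def rect_mask(h, w, pad=2):
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad:pad + h, pad:pad + w] = True
    return BinaryMask(m)
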