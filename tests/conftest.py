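import numpy as np
import pytest

from xcoloc import Mask, SceneConfig, ScaledImage, gaussian_psf, generate_scene

VOXEL = 0.0754  # µm, the lateral sampling used throughout the synthetic scenes


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def ring_scene_2d():
    """2-D paired-point scene: 30 pairs at 2.32 µm, random orientations."""
    config = SceneConfig(
        shape=(128, 128), scale=(0.1, 0.1), n_pairs=30, scd=2.32, seed=3
    )
    psf = gaussian_psf(0.3, None, (0.1, 0.1))
    return generate_scene(config, psf), config


@pytest.fixture
def small_scene_3d():
    """Small 3-D paired-point scene for pipeline-level tests."""
    config = SceneConfig(
        shape=(16, 48, 48),
        scale=(VOXEL,) * 3,
        n_pairs=10,
        scd=0.6,
        seed=11,
    )
    psf = gaussian_psf(0.25, 0.25, (VOXEL,) * 3)
    return generate_scene(config, psf), config


def random_image(rng, shape, scale=None):
    scale = scale or (0.1,) * len(shape)
    return ScaledImage(rng.normal(size=shape), scale)


@pytest.fixture
def full_mask():
    def _make(shape):
        return Mask(np.ones(shape, dtype=bool))

    return _make
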