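"""Pixel-randomization null model for non-specific correlation.

A raw cross-correlation volume mixes true, distance-specific correlation with
correlation that any two images with the same marginal intensity layout would
show (low-spatial-frequency repeating structure, overall density).  To
estimate that non-specific component, the in-mask voxels of the first image
are randomly permuted to other in-mask sites and re-correlated with the
untouched second image; averaging over several independent permutations gives
the expected non-specific correlation volume.  Subtracting it from the raw
correlation leaves only the specific component, whose spatial mean is close
to zero because permutation preserves the total in-mask intensity exactly.

Permutation (sampling without replacement) rather than independent
resampling is deliberate: it conserves the intensity multiset, not just its
mean.  Only the first image is randomized; which input plays that role is
simply the first positional argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationVolume, _FFTCorrelator
from .image_model import Mask, ScaledImage

__all__ = ["NullModel", "randomize_within_mask", "build_null", "subtract_null"]

DEFAULT_CYCLES = 10


@dataclass
class NullModel:
    """Averaged non-specific correlation volume plus the run parameters."""

    cycles: int
    seed: int
    mean_null: CorrelationVolume

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


def randomize_within_mask(
    img: ScaledImage, mask: Mask, rng: np.random.Generator
) -> ScaledImage:
    """Permute the in-mask voxel values uniformly at random.

    Out-of-mask voxels are zeroed; the in-mask value multiset (hence the
    total image intensity) is preserved exactly.
    """
    if mask.shape != img.spatial_shape:
        raise ValueError("mask shape mismatch")
    if img.has_time:
        raise ValueError("randomize single frames, not time series")
    out = np.zeros_like(img.data)
    values = img.data[mask.data]
    out[mask.data] = rng.permutation(values)
    return ScaledImage(out, img.scale)


def build_null(
    img1: ScaledImage,
    img2: ScaledImage,
    mask: Mask,
    cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
) -> NullModel:
    """Average of ``cycles`` randomize-and-correlate passes.

    Per-cycle RNG streams are spawned deterministically from ``seed``, so a
    fixed seed reproduces the null bit-for-bit while cycles stay independent.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if img1.spatial_shape != img2.spatial_shape or img1.scale != img2.scale:
        raise ValueError("images must share shape and scale")
    correlator = _FFTCorrelator(img2.data)
    streams = np.random.SeedSequence(seed).spawn(cycles)
    acc = np.zeros(img1.spatial_shape)
    for child in streams:
        rng = np.random.default_rng(child)
        randomized = randomize_within_mask(img1, mask, rng)
        acc += correlator.correlate(randomized.data)
    acc /= cycles
    center = tuple(n // 2 for n in acc.shape)
    return NullModel(cycles, seed, CorrelationVolume(acc, center, img1.scale))


def subtract_null(ccr: CorrelationVolume, null: NullModel) -> CorrelationVolume:
    """Specific correlation volume: raw correlation minus the averaged null."""
    mean_null = null.mean_null
    if ccr.shape != mean_null.shape or ccr.center_index != mean_null.center_index:
        raise ValueError("correlation volume and null model do not align")
    return CorrelationVolume(
        ccr.data - mean_null.data, ccr.center_index, ccr.scale
    )
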