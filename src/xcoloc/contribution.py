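"""Reconstruction of the signal that drove the fitted correlation.

Unlike pixel-wise colocalization, where every scatterplot point maps back to
one pixel, every voxel of both inputs contributes to every voxel of a
cross-correlation volume.  To visualize *which* original signal produced the
fitted correlation peak, the specific correlation volume is first weighted
by the fitted Gaussian evaluated at each voxel's physical distance from the
zero-shift center (the GCCR) — suppressing everything except shifts at the
fitted correlation distance — and the GCCR is then used as a kernel to
project each image's signal onto the other:

* ``cont_img1``: the GCCR, applied to img2, highlights every location that
  sits at the fitted distance (in a contributing orientation) from img2
  signal; multiplying voxel-wise by img1 keeps only img1 signal at such
  locations.
* ``cont_img2``: the same with the roles reversed, which requires the
  mirrored kernel because the shift convention reverses sign when the
  images swap roles.

Intensities in the contribution images therefore depend on orientation as
well as distance: pairs sharing an orientation reinforce the same shift
voxel of the GCCR and come out brighter than a pair with a unique
orientation.  Outputs are raw signed floats — negatives flag places where
the averaged null exceeded the raw correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import (
    CorrelationVolume,
    convolve_kernel,
    correlate_kernel,
)
from .image_model import ScaledImage
from .profile_fit import GaussianFit

__all__ = ["ContributionPair", "gaussian_modify", "contribution_images"]


@dataclass
class ContributionPair:
    cont_img1: ScaledImage
    cont_img2: ScaledImage
    gccr: CorrelationVolume


def gaussian_modify(sccr: CorrelationVolume, fit: GaussianFit) -> CorrelationVolume:
    """Weight each voxel by the unit-peak fitted Gaussian at its distance.

    The amplitude is dropped (unit peak): only the relative weighting
    matters, and a unit peak keeps the product images on the intensity
    scale of the inputs.  Voxels at the fitted distance are untouched;
    a few sigma away they are suppressed to nothing.
    """
    if not fit.valid:
        raise ValueError("cannot Gaussian-modify with an invalid fit")
    d = sccr.distances()
    weights = np.exp(-((d - fit.mu) ** 2) / (2.0 * fit.sigma**2))
    return CorrelationVolume(sccr.data * weights, sccr.center_index, sccr.scale)


def contribution_images(
    img1: ScaledImage, img2: ScaledImage, gccr: CorrelationVolume
) -> ContributionPair:
    """Project the Gaussian-weighted correlation back onto both inputs.

    The voxel-wise product guarantees support containment: a contribution
    image is exactly zero wherever its source image is zero.
    """
    if img1.spatial_shape != img2.spatial_shape:
        raise ValueError("image shapes differ")
    if gccr.shape != img1.spatial_shape:
        raise ValueError("correlation volume shape differs from images")
    kernel = ScaledImage(gccr.data, gccr.scale)
    # img1 at x pairs img2 at x+s, so img2 is probed at +s (correlation)
    # and img1 at -s (convolution) relative to each voxel.
    reach1 = correlate_kernel(img2, kernel)
    reach2 = convolve_kernel(img1, kernel)
    cont1 = ScaledImage(reach1.data * img1.data, img1.scale)
    cont2 = ScaledImage(reach2.data * img2.data, img2.scale)
    return ContributionPair(cont1, cont2, gccr)
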