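"""FFT-backed cross-correlation, autocorrelation and kernel operations.

All correlations are *linear* (zero-padded), never circular: padded FFT
lengths are chosen per axis as ``next_fast_len(2n - 1)`` so that wrap-around
cannot create spurious long-distance correlations, then the result is cropped
back to the input shape.  The output voxel at ``center_index = shape // 2``
corresponds to zero relative shift, and a voxel at offset ``s`` from the
center holds

    result(s) = sum_x img1(x) * img2(x + s)

i.e. translating img2 by ``+v`` relative to img1 moves the correlation peak
to ``center_index + v``.  Shifts beyond half the field of view per axis are
not represented, which bounds the maximum measurable correlation distance.

Raw correlation sums are kept (no per-shift overlap normalization): the
downstream confidence ratio and Gaussian fit are unaffected by a global
scale, and the analysis mask keeps signal away from the borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import irfftn, next_fast_len, rfftn

from .image_model import ScaledImage

__all__ = [
    "CorrelationVolume",
    "cross_correlate",
    "auto_correlate",
    "convolve_kernel",
    "correlate_kernel",
]


@dataclass
class CorrelationVolume:
    """Correlation values indexed by shift vector, center = zero shift."""

    data: np.ndarray
    center_index: tuple[int, ...]
    scale: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.center_index = tuple(int(c) for c in self.center_index)
        self.scale = tuple(float(s) for s in self.scale)
        if len(self.center_index) != self.data.ndim:
            raise ValueError("center_index rank mismatch")
        for c, n in zip(self.center_index, self.data.shape):
            if not 0 <= c < n:
                raise ValueError("center_index outside the array")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def distances(self) -> np.ndarray:
        """Physical (µm) distance of every voxel from the zero-shift center."""
        grids = np.meshgrid(
            *[
                (np.arange(n) - c) * s
                for n, c, s in zip(self.shape, self.center_index, self.scale)
            ],
            indexing="ij",
        )
        return np.sqrt(sum(g * g for g in grids))


def _check_pair(img1: ScaledImage, img2: ScaledImage) -> None:
    if img1.has_time or img2.has_time:
        raise ValueError("correlate single frames, not time series")
    if img1.spatial_shape != img2.spatial_shape:
        raise ValueError(
            f"shape mismatch: {img1.spatial_shape} vs {img2.spatial_shape}"
        )
    if img1.scale != img2.scale:
        raise ValueError(f"scale mismatch: {img1.scale} vs {img2.scale}")


class _FFTCorrelator:
    """Zero-padded FFT correlator that caches the spectrum of the fixed image.

    The randomization null re-correlates many permuted copies of the first
    image against the same second image; caching ``F(img2)`` saves one large
    forward transform per cycle.
    """

    def __init__(self, img2_data: np.ndarray):
        self.shape = img2_data.shape
        self.fshape = tuple(next_fast_len(2 * n - 1) for n in self.shape)
        self.f2 = rfftn(img2_data, self.fshape)
        # per-axis circular indices mapping output voxel -> shift (mod L)
        self._idx = tuple(
            (np.arange(n) - n // 2) % L for n, L in zip(self.shape, self.fshape)
        )

    def correlate(self, img1_data: np.ndarray) -> np.ndarray:
        if img1_data.shape != self.shape:
            raise ValueError("shape mismatch")
        f1 = rfftn(img1_data, self.fshape)
        full = irfftn(np.conj(f1) * self.f2, self.fshape)
        return full[np.ix_(*self._idx)]


def cross_correlate(img1: ScaledImage, img2: ScaledImage) -> CorrelationVolume:
    """Linear cross-correlation of two equally-shaped, mask-modified images."""
    _check_pair(img1, img2)
    corr = _FFTCorrelator(img2.data).correlate(img1.data)
    center = tuple(n // 2 for n in corr.shape)
    return CorrelationVolume(corr, center, img1.scale)


def auto_correlate(img: ScaledImage) -> CorrelationVolume:
    """Normalized autocorrelation: zero-shift value is exactly 1.

    The full area under its radial profile is the package's autocorrelation
    measure — large values flag dense signal or low resolution, both of which
    depress the confidence statistic.
    """
    vol = cross_correlate(img, img)
    center_value = vol.data[vol.center_index]
    if center_value == 0:
        raise ValueError("cannot normalize the autocorrelation of a zero image")
    vol.data = vol.data / center_value
    vol.data[vol.center_index] = 1.0
    return vol


def _check_kernel(img: ScaledImage, kernel: ScaledImage) -> None:
    if img.has_time or kernel.has_time:
        raise ValueError("kernel operations take single frames")
    if img.scale != kernel.scale:
        raise ValueError(f"scale mismatch: {img.scale} vs {kernel.scale}")
    if any(k > n for k, n in zip(kernel.spatial_shape, img.spatial_shape)):
        raise ValueError("kernel larger than image")


def convolve_kernel(img: ScaledImage, kernel: ScaledImage) -> ScaledImage:
    """Linear convolution cropped to the image extent.

    The kernel is treated as centered at ``kernel.shape // 2`` (matching the
    zero-shift center of a correlation volume used as a kernel), so a unit
    impulse at that voxel is the identity.
    """
    _check_kernel(img, kernel)
    full = signal.fftconvolve(img.data, kernel.data, mode="full")
    starts = [k // 2 for k in kernel.spatial_shape]
    slices = tuple(
        slice(s, s + n) for s, n in zip(starts, img.spatial_shape)
    )
    return ScaledImage(full[slices], img.scale)


def correlate_kernel(img: ScaledImage, kernel: ScaledImage) -> ScaledImage:
    """Correlation with a kernel: convolution with the mirrored kernel.

    Mirroring reverses every axis about the kernel center, so
    ``out(i) = sum_j img(i + j - c) * kernel(j)`` with ``c = shape // 2``.
    """
    _check_kernel(img, kernel)
    full = signal.correlate(img.data, kernel.data, mode="full", method="fft")
    starts = [k - 1 - k // 2 for k in kernel.spatial_shape]
    slices = tuple(
        slice(s, s + n) for s, n in zip(starts, img.spatial_shape)
    )
    return ScaledImage(full[slices], img.scale)
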