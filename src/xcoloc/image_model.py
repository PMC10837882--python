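"""Scaled-image data model, TIFF I/O and pre-processing.

The unit of analysis throughout the package is a :class:`ScaledImage`: an
intensity volume together with the physical voxel size of every spatial axis,
in micrometres.  Accurate per-axis scaling metadata is a hard requirement —
every distance the package reports (the fitted correlation distance and its
spread) is computed from these values, so a missing or zero voxel size is an
error rather than a silent default of 1.

Two pre-processing steps are deliberately explicit rather than automatic:

* conversion to a signed representation plus subtraction of the mean
  background level (unsigned formats clamp at zero, which leaves a positive
  residual background that destroys the confidence statistic), and
* construction of a binary analysis mask that separates foreground from
  background (blur + Otsu threshold, optionally minus an exclusion mask).

Axis convention: spatial axes are ordered ``(z, y, x)`` for 3-D data and
``(y, x)`` for 2-D; an optional time axis always leads.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ScaledImage",
    "Mask",
    "PreprocessReport",
    "read_image",
    "write_image",
    "subtract_background",
    "zero_clip",
    "make_mask",
    "apply_mask",
]


@dataclass
class ScaledImage:
    """An intensity volume with physical voxel sizes.

    Parameters
    ----------
    data
        Real-valued intensities, stored as float64.  Negative values are
        allowed (and required after background subtraction).
    scale
        Physical size of one voxel along each *spatial* axis, in µm,
        ordered like the spatial axes of ``data``.
    has_time
        If true, the leading axis of ``data`` is time and is excluded from
        ``scale``.
    """

    data: np.ndarray
    scale: tuple[float, ...]
    has_time: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.scale = tuple(float(s) for s in self.scale)
        ndim_spatial = self.data.ndim - (1 if self.has_time else 0)
        if ndim_spatial not in (2, 3):
            raise ValueError(
                f"expected 2 or 3 spatial axes, got {ndim_spatial}"
            )
        if len(self.scale) != ndim_spatial:
            raise ValueError(
                f"scale has {len(self.scale)} entries for "
                f"{ndim_spatial} spatial axes"
            )
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"voxel sizes must be positive, got {self.scale}")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:] if self.has_time else self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.has_time else 1

    def frame(self, i: int) -> "ScaledImage":
        """Return frame ``i`` as a single-frame image (identity if no time axis)."""
        if not self.has_time:
            if i != 0:
                raise IndexError("image has no time axis")
            return self
        return ScaledImage(self.data[i], self.scale)

    @property
    def axes(self) -> str:
        spatial = "zyx" if len(self.scale) == 3 else "yx"
        return ("t" + spatial) if self.has_time else spatial


@dataclass
class Mask:
    """Binary analysis mask; any nonzero voxel of the source counts as foreground."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.foreground_count < 2:
            raise ValueError(
                "mask must contain at least 2 foreground voxels "
                f"(got {self.foreground_count})"
            )

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class PreprocessReport:
    mean_background_subtracted: float
    converted_to_signed: bool = True


def _scale_to_rational(s: float) -> tuple[int, int]:
    # XResolution is voxels per unit, stored as a ratio of two uint32.
    # A best rational approximation with denominator <= 1e9 keeps both
    # integers in range while staying within half an ulp of the float
    # voxel size, so the scale round-trips bit-for-bit.
    frac = Fraction(s).limit_denominator(10**9)
    return frac.denominator, frac.numerator


def write_image(img: ScaledImage, path) -> None:
    """Write a 32-bit float TIFF carrying the voxel-size metadata.

    Lateral (x, y) sizes go into the TIFF resolution tags as exact rationals;
    the z spacing goes into ImageJ-style metadata, so both dialects read the
    file correctly and ``read_image(write_image(img))`` reproduces data and
    scale exactly (for float32-representable data).
    """
    data = img.data.astype(np.float32)
    sx = img.scale[-1]
    sy = img.scale[-2]
    metadata = {"axes": img.axes.upper(), "unit": "um"}
    if len(img.scale) == 3:
        metadata["spacing"] = img.scale[0]
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(_scale_to_rational(sx), _scale_to_rational(sy)),
        metadata=metadata,
    )


def read_image(path, scale_override: Optional[Sequence[float]] = None) -> ScaledImage:
    """Read a grayscale TIFF into a :class:`ScaledImage`.

    Voxel sizes are taken from the TIFF resolution tags (x, y) and the
    ImageJ ``spacing`` field (z).  ``scale_override`` replaces all metadata;
    without it, missing or zero voxel sizes raise rather than defaulting.

    Data is promoted to float64 so that subsequent arithmetic (background
    subtraction, correlation sums) is signed and well conditioned regardless
    of the input bit depth.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        page = tif.pages[0]
        ij = tif.imagej_metadata or {}

        has_time = "T" in axes
        ndim_spatial = data.ndim - (1 if has_time else 0)
        if ndim_spatial not in (2, 3):
            raise ValueError(
                f"{path}: expected 2 or 3 spatial axes "
                f"(optionally + time), got array shape {data.shape} ({axes})"
            )

        if scale_override is not None:
            scale = tuple(float(s) for s in scale_override)
            if len(scale) != ndim_spatial:
                raise ValueError(
                    f"scale override has {len(scale)} entries for "
                    f"{ndim_spatial} spatial axes"
                )
            return ScaledImage(data, scale, has_time=has_time)

        def _res_to_size(tag_name: str) -> Optional[float]:
            tag = page.tags.get(tag_name)
            if tag is None:
                return None
            num, den = tag.value
            if num == 0:
                return None
            return den / num  # tag stores voxels per unit

        sx = _res_to_size("XResolution")
        sy = _res_to_size("YResolution")
        sz = ij.get("spacing")
        if sx == 1.0 and sy == 1.0 and not ij:
            # bare files carry a default 1 pixel/unit resolution with no
            # declared unit: that is absent calibration, not a 1 µm voxel
            sx = sy = None
        if sx is None or sy is None or (ndim_spatial == 3 and not sz):
            raise ValueError(
                f"{path}: voxel-size metadata missing or zero; pass an "
                "explicit scale override"
            )
        scale = (float(sz), float(sy), float(sx)) if ndim_spatial == 3 else (
            float(sy),
            float(sx),
        )
    return ScaledImage(data, scale, has_time=has_time)


def subtract_background(
    img: ScaledImage, mean_background: float
) -> tuple[ScaledImage, PreprocessReport]:
    """Subtract a flat mean background level, keeping negative values.

    Clamping at zero would leave a positive residual background and collapse
    the confidence statistic, so the result is signed.
    """
    out = ScaledImage(img.data - float(mean_background), img.scale, img.has_time)
    return out, PreprocessReport(float(mean_background))


def zero_clip(img: ScaledImage) -> ScaledImage:
    """Set negative intensities to zero.

    Provided only to emulate unsigned image handling; it degrades the
    analysis (zero-bounded noise behaves like added background) and is never
    applied by the pipeline itself.
    """
    return ScaledImage(np.maximum(img.data, 0.0), img.scale, img.has_time)


def make_mask(
    img: ScaledImage, blur_radius: float, exclude: Optional[Mask] = None
) -> Mask:
    """Gaussian-blur + Otsu threshold foreground mask.

    ``blur_radius`` is an isotropic radius in voxels (0 disables blurring).
    If ``exclude`` is given its foreground is removed from the result, e.g.
    subtracting a nuclear mask from a cytoplasm mask.
    """
    if img.has_time:
        raise ValueError("build masks from a single frame, not a time series")
    if blur_radius < 0:
        raise ValueError("blur_radius must be >= 0")
    blurred = (
        ndimage.gaussian_filter(img.data, sigma=blur_radius)
        if blur_radius > 0
        else img.data
    )
    if np.min(blurred) == np.max(blurred):
        raise ValueError("constant image: Otsu threshold is undefined")
    thresh = threshold_otsu(blurred)
    fg = blurred > thresh
    if exclude is not None:
        if exclude.shape != fg.shape:
            raise ValueError("exclude mask shape mismatch")
        fg &= ~exclude.data
    return Mask(fg)


def apply_mask(img: ScaledImage, mask: Mask) -> ScaledImage:
    """Zero every voxel outside the mask so it cannot contribute to correlation."""
    if mask.shape != img.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} != image spatial shape {img.spatial_shape}"
        )
    out = img.data * mask.data  # broadcasts over a leading time axis
    return ScaledImage(out, img.scale, img.has_time)
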