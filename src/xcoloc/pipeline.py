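"""Full analysis pipeline for single frames and time series.

``run_ccc`` chains the stages: mask-modify both images, raw cross-correlate,
build the randomization null, subtract it, reduce both volumes to radial
profiles, fit the Gaussian, compute R² / confidence / autocorrelation areas,
and (for a valid fit) reconstruct the contribution images.  The whole chain
is deterministic for a fixed seed and cycle count.

Pre-processing (signed conversion, background subtraction, mask
construction) is deliberately *not* performed here: those steps change the
meaning of the result and must be applied explicitly by the caller or the
CLI, so that a user always knows what was subtracted.

Time series are analyzed frame by frame with per-frame derived seeds; the
per-frame specific-correlation profiles are stacked into a frame-by-distance
heatmap and the frame with the highest confidence is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .contribution import ContributionPair, contribution_images, gaussian_modify
from .correlation import CorrelationVolume, auto_correlate, cross_correlate
from .image_model import Mask, ScaledImage, apply_mask, write_image
from .profile_fit import (
    SENTINEL,
    CorrelationStats,
    GaussianFit,
    RadialProfile,
    autocorr_area,
    confidence,
    fit_gaussian,
    profile_table,
    r_squared,
    radial_profile,
)
from .randomization import DEFAULT_CYCLES, build_null, subtract_null

__all__ = ["CCCResult", "TimeSeriesResult", "run_ccc", "run_ccc_timeseries", "write_results"]

logger = logging.getLogger(__name__)


@dataclass
class CCCResult:
    """All outputs of one single-frame analysis."""

    fit: GaussianFit
    stats: CorrelationStats
    ccr_profile: RadialProfile
    null_profile: RadialProfile
    sccr_profile: RadialProfile
    sccr: CorrelationVolume
    contributions: Optional[ContributionPair]
    cycles: int
    seed: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "mu_um": self.fit.mu if self.fit.valid else SENTINEL,
                "sigma_um": self.fit.sigma if self.fit.valid else SENTINEL,
                "confidence": self.stats.confidence,
                "r_squared": self.stats.r_squared,
                "autocorr_area_1": self.stats.autocorr_area_1,
                "autocorr_area_2": self.stats.autocorr_area_2,
                "fit_valid": self.fit.valid,
                "cycles": self.cycles,
                "seed": self.seed,
            }
        )


@dataclass
class TimeSeriesResult:
    per_frame: list[CCCResult]
    heatmap: np.ndarray  # (frame, distance bin) of specific-correlation profiles
    best_frame: Optional[int]  # None when every frame failed to fit


def run_ccc(
    img1: ScaledImage,
    img2: ScaledImage,
    mask: Mask,
    cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
    compute_contributions: bool = True,
    compute_autocorr: bool = True,
) -> CCCResult:
    """Measure the spatial correlation between two images as a distance.

    Inputs must already be pre-processed (signed, background-subtracted).
    A failed Gaussian fit produces a sentinel result (confidence = R² = -1,
    no contribution images), never an exception.
    """
    if img1.has_time or img2.has_time:
        raise ValueError("run_ccc analyzes single frames; see run_ccc_timeseries")
    if img1.spatial_shape != img2.spatial_shape or img1.scale != img2.scale:
        raise ValueError("images must share shape and scale")
    m1 = apply_mask(img1, mask)
    m2 = apply_mask(img2, mask)
    logger.info(
        "run_ccc: seed=%d cycles=%d mask_fraction=%.4f",
        seed,
        cycles,
        mask.foreground_count / float(np.prod(mask.shape)),
    )

    ccr = cross_correlate(m1, m2)
    null = build_null(m1, m2, mask, cycles=cycles, seed=seed)
    sccr = subtract_null(ccr, null)

    ccr_rp = radial_profile(ccr)
    null_rp = radial_profile(null.mean_null)
    sccr_rp = radial_profile(sccr)

    fit = fit_gaussian(sccr_rp)
    r2 = r_squared(sccr_rp, fit)
    conf = confidence(sccr_rp, ccr_rp, fit)

    area1 = area2 = float("nan")
    if compute_autocorr:
        for name, m in (("autocorr_area_1", m1), ("autocorr_area_2", m2)):
            try:
                area = autocorr_area(radial_profile(auto_correlate(m)))
            except ValueError:
                area = float("nan")
            if name.endswith("1"):
                area1 = area
            else:
                area2 = area
    stats = CorrelationStats(conf, r2, area1, area2)

    contributions = None
    if fit.valid and compute_contributions:
        gccr = gaussian_modify(sccr, fit)
        contributions = contribution_images(m1, m2, gccr)

    return CCCResult(
        fit, stats, ccr_rp, null_rp, sccr_rp, sccr, contributions, cycles, seed
    )


def run_ccc_timeseries(
    stack1: ScaledImage,
    stack2: ScaledImage,
    mask: Mask,
    cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
    compute_contributions: bool = True,
    frame_seeds=None,
) -> TimeSeriesResult:
    """Analyze each frame independently and aggregate the profiles.

    Per-frame randomization seeds are derived from ``seed`` (or supplied
    explicitly via ``frame_seeds``) so frames stay independent yet the
    whole run is reproducible.  ``best_frame`` is the earliest frame
    attaining the maximum confidence among valid fits.
    """
    if stack1.n_frames != stack2.n_frames:
        raise ValueError("frame counts differ")
    if frame_seeds is None:
        frame_seeds = np.random.SeedSequence(seed).generate_state(stack1.n_frames)
    elif len(frame_seeds) != stack1.n_frames:
        raise ValueError("frame_seeds length must equal the frame count")
    results = []
    for i in range(stack1.n_frames):
        res = run_ccc(
            stack1.frame(i),
            stack2.frame(i),
            mask,
            cycles=cycles,
            seed=int(frame_seeds[i] & 0x7FFFFFFF),
            compute_contributions=compute_contributions,
        )
        results.append(res)
    heatmap = np.stack([r.sccr_profile.values for r in results])
    best_frame: Optional[int] = None
    best_conf = -np.inf
    for i, r in enumerate(results):
        if r.fit.valid and r.stats.confidence > best_conf:
            best_conf = r.stats.confidence
            best_frame = i
    return TimeSeriesResult(results, heatmap, best_frame)


def _write_volume(vol: CorrelationVolume, path: Path) -> None:
    write_image(ScaledImage(vol.data, vol.scale), path)


def _write_single(result: CCCResult, outdir: Path) -> None:
    result.summary().to_frame().T.to_csv(outdir / "summary.csv", index=False)
    profile_table(
        result.ccr_profile, result.null_profile, result.sccr_profile, result.fit
    ).to_csv(outdir / "radial_profile.csv", index=False)
    _write_volume(result.sccr, outdir / "sccr.tif")
    if result.contributions is not None:
        _write_volume(result.contributions.gccr, outdir / "gccr.tif")
        write_image(result.contributions.cont_img1, outdir / "contribution_img1.tif")
        write_image(result.contributions.cont_img2, outdir / "contribution_img2.tif")


def write_results(result, outdir) -> None:
    """Write the documented file set for a single-frame or time-series result.

    Single frame: ``summary.csv``, ``radial_profile.csv``, ``sccr.tif`` and,
    for a valid fit, ``gccr.tif`` + the two contribution TIFFs.  Time
    series: one ``frame_NNN/`` directory per frame with the same layout,
    plus an aggregated ``summary.csv`` (one row per frame, best frame
    flagged) and the frame-by-distance ``heatmap.tif``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, CCCResult):
        _write_single(result, outdir)
        return
    if not isinstance(result, TimeSeriesResult):
        raise TypeError(f"cannot write a {type(result).__name__}")
    rows = []
    for i, frame_result in enumerate(result.per_frame):
        framedir = outdir / f"frame_{i:03d}"
        framedir.mkdir(exist_ok=True)
        _write_single(frame_result, framedir)
        row = frame_result.summary()
        row["frame"] = i
        row["best_frame"] = i == result.best_frame
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
    tifffile.imwrite(outdir / "heatmap.tif", result.heatmap.astype(np.float32))
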