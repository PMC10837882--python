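# xcoloc — colocalization by cross-correlation

Measures the spatial correlation between two fluorescently labeled
structures in 2-D or 3-D microscopy images **as a function of physical
distance**, rather than as pixel overlap. Classic colocalization metrics
(Pearson's R and friends) require the two signals to overlap, so they get
*worse* as resolution improves and fail outright for structures that sit
near each other without touching — exactly the regime super-resolution
imaging creates. Cross-correlation over all spatial shifts has no overlap
requirement: two structures a fixed distance apart produce a correlation
peak at that distance.

## Method

Given two images `img1`, `img2` (signed, background-subtracted, with
accurate per-axis voxel sizes) and a binary analysis mask:

1. Voxels outside the mask are zeroed in both images.
2. The raw cross-correlation volume `CCR(s) = Σ_x img1(x)·img2(x+s)` is
   computed by zero-padded FFT for every shift `s` up to half the field of
   view; the volume's center is zero shift.
3. A null model of non-specific correlation is built by repeatedly
   permuting the in-mask voxels of `img1` to random in-mask sites,
   re-correlating against the untouched `img2`, and averaging
   (default 10 cycles). Subtracting it leaves the specific correlation,
   `SCCR = CCR − ⟨null⟩`; permutation preserves total intensity exactly, so
   the SCCR averages to ≈ 0 and only distance-specific structure survives.
4. The SCCR is reduced to a radial profile over physical distance and a
   Gaussian `A·exp(−(d−µ)²/2σ²)` is fitted (a Gaussian approximates a point
   spread function). **µ** is the mean correlation distance and **σ** its
   spread, both in µm.
5. Two statistics qualify the fit, both over `µ ± 3σ`:
   **confidence** `= ∫SCCR_RP / ∫CCR_RP ∈ [0, 1]` (the fraction of
   correlation at the fitted distance that is specific) and **R²** of the
   Gaussian against the profile. A failed fit reports both as −1.
6. Weighting the SCCR by the fitted Gaussian at each voxel's distance
   gives the GCCR, which is projected back onto each input to produce two
   *contribution images* showing exactly which signal drove the result.

Time series are analyzed frame by frame; the per-frame profiles are stacked
into a frame × distance heatmap and the highest-confidence frame reported.

A bundled generator renders the validation scenes: single-voxel points
paired across the two channels at a set distance with random orientation,
PSF blur, optional uncorrelated points, flat background, and Gaussian
noise, with full ground truth.

## Worked example

```python
from xcoloc import SceneConfig, gaussian_psf, generate_scene, run_ccc

config = SceneConfig(
    shape=(128, 128), scale=(0.1, 0.1), n_pairs=30, scd=2.32, seed=3
)
psf = gaussian_psf(lateral_fwhm=0.3, axial_fwhm=None, scale=config.scale)
img1, img2, mask, truth = generate_scene(config, psf)

result = run_ccc(img1, img2, mask, cycles=10, seed=5)
print(f"true separation : {truth.scd:.2f} um")
print(f"fitted mu       : {result.fit.mu:.3f} um")
print(f"fitted sigma    : {result.fit.sigma:.3f} um")
print(f"confidence      : {result.stats.confidence:.3f}")
print(f"R^2             : {result.stats.r_squared:.3f}")
```

prints

```
true separation : 2.32 um
fitted mu       : 2.364 um
fitted sigma    : 0.190 um
confidence      : 0.279
R^2             : 0.981
```

The 30 point pairs never overlap (their Pearson correlation is ≈ 0), yet
the fitted distance lands within half a voxel of the true 2.32 µm
separation. The confidence of 0.28 reflects how much of the correlation at
that distance survives the randomization null — on real data, values above
0.1 indicate a reasonably likely true correlation.

## Command line

```sh
xcoloc run IMG1 IMG2 --mask MASK --cycles 10 --seed 1 --out results/
xcoloc simulate --config scene.cfg --out scene/
xcoloc benchmark --config scene.cfg --reps 10 --out bench/
```

`run` reads TIFFs (voxel sizes from resolution tags / ImageJ spacing, or
`--scale z,y,x`), writes a summary CSV, the radial-profile table, and the
SCCR/GCCR/contribution TIFFs. `--time-series` analyzes a stack frame by
frame. Background subtraction is explicit (`--subtract-background`),
never silent.

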