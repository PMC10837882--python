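# Methods

## Model and assumptions

The package measures the spatial correlation between two fluorescence
images as a function of physical distance. The underlying model is that
the imaged structures are ensembles of point-like emitters blurred by the
microscope's point spread function (PSF), and that a true spatial relation
between the two labels manifests as an excess of cross-correlation at a
characteristic shift distance. Three assumptions follow:

* **Single correlation scale.** One Gaussian is fitted to the radial
  profile of the specific correlation; multi-modal relations are not
  modeled (the exported profile table lets users fit their own model).
* **Gaussian-like peak shape.** The correlation peak of PSF-blurred point
  pairs is approximately Gaussian because the PSF is; strongly aberrated
  or side-lobed PSFs will depress R² but not usually bias µ.
* **Adequate mask.** The analysis mask must cover the possible locations
  of the labeled structures. The randomization null permutes intensities
  only within the mask, so structure *shared* by both channels that the
  mask encodes (e.g. a repeating pattern of cells) is absorbed into the
  null and removed; an overly restrictive mask instead removes the signal
  itself and drives the result to low confidence or a fit failure.

Distances are physical throughout: every voxel's offset from the
zero-shift center is scaled by the per-axis voxel size (µm) before any
binning or fitting. Missing voxel-size metadata is an error, never a
silent default.

## Pipeline and conventions

`run_ccc` chains: mask-modify → FFT cross-correlation → randomization
null → subtraction → radial profiles → Gaussian fit → R² / confidence →
contribution images.

* **Correlation convention.** `CCR(s) = Σ_x img1(x)·img2(x+s)`; the output
  volume has the input shape with zero shift at `shape // 2`, so the
  maximum measurable distance is half the field of view per axis.
* **Linear, not circular.** FFT lengths are padded to at least `2n − 1`
  per axis (rounded up to fast sizes) and cropped back, so wrap-around
  cannot fabricate long-distance correlation. Zero extension beyond the
  image border is assumed.
* **Raw sums.** No per-shift overlap normalization is applied: the
  confidence ratio and the Gaussian location are invariant to a global
  scale, and the mask keeps signal away from the borders where the
  overlap taper matters.
* **Contribution images.** With the convention above, img1 signal at `x`
  pairs with img2 signal at `x + s`, so the Gaussian-weighted correlation
  volume (GCCR) probes img2 by a correlation operation and img1 by a
  convolution; each highlight map is then multiplied voxel-wise by its
  own image, which guarantees exact support containment. The GCCR is
  used with unit peak height so contributions stay on the intensity
  scale of the inputs; outputs are raw signed floats (negatives flag
  places where the null exceeded the raw correlation).

## Randomization null

Non-specific correlation is estimated by permuting the in-mask voxels of
the *first* image uniformly at random (sampling without replacement, so
the intensity multiset — hence the total intensity — is conserved
exactly), re-correlating against the unmodified second image, and
averaging over `cycles` independent permutations.

* `cycles` (default **10**): the Monte-Carlo error of the averaged null
  shrinks as `1/√cycles`; 10 is the value used throughout the reference
  evaluation protocol and is a good cost/precision compromise at typical
  image sizes.
* Per-cycle RNG streams are spawned deterministically from one master
  seed, so results are bit-reproducible; the seed is recorded in every
  result and output file.
* Only one image is randomized; which one is simply the first positional
  argument. The same averaged null serves both the SCCR and the
  confidence denominator.

## Radial profile and Gaussian fit

* **Bin width** = the smallest per-axis voxel size — the finest physically
  meaningful resolution. Voxels are assigned to the nearest bin center
  (centers at integer multiples of the width); bin values are arithmetic
  means, so total mass is conserved.
* **Count-weighted fitting.** The least squares weights each bin by
  `√count`: a bin mean over `count` voxels has variance ∝ 1/count, and
  the bins nearest zero shift are nearly empty (the d = 0 bin holds a
  single voxel). Unweighted fitting lets those bins dominate noisy
  profiles and the fit locks onto single-bin spikes; weighting restores
  the physically sensible ordering in which noise first degrades fit
  quality (R²) and only much later destabilizes µ. R² itself is
  *unweighted*.
* **Initialization and retries.** Candidate starts are the profile's
  local maxima ranked by `value·√count` (weighted significance, again to
  avoid near-empty-bin spikes). The fit starts from the best-ranked peak
  with a half-width-based σ guess; the first converged attempt is
  accepted, exact rank ties are broken by the lower weighted residual,
  and up to 8 candidates are tried before declaring failure.
* **Bounds.** A > 0 (a negative correlation peak is meaningless),
  µ ∈ [0, d_max], σ ∈ (0, d_max]. Fit failure is a value
  (`valid = False`, confidence = R² = −1), never an exception. An exactly
  featureless input (constant within the mask) short-circuits: its
  randomization is the identity, the SCCR vanishes identically, and the
  sentinel path fires deterministically.
* **Windows.** R² and confidence are evaluated over bins with centers in
  `[max(0, µ−3σ), µ+3σ]` — the lower clip because radial distance is
  non-negative. Both confidence integrals use the same trapezoidal rule
  so discretization bias cancels; the ratio is clamped to [0, 1] (noisy
  nulls can push the raw ratio slightly outside). A zero denominator
  yields confidence 0; a window with a single bin yields 0 rather than a
  0/0.
* **Autocorrelation area**: trapezoidal area under the full radial
  profile of each channel's normalized autocorrelation (zero-shift value
  exactly 1). High values flag dense signal or low resolution, the
  regimes in which confidence is inherently low.

## Synthetic scenes

The generator reproduces the structure of the reference validation data:
unit-intensity single-voxel points paired across the two channels at a set
physical distance (SCD) with uniformly random orientation (sphere in 3-D,
circle in 2-D), partner positions rounded to the voxel grid (realized
distances are therefore within one voxel diagonal of the SCD, and ground
truth records every placement); optional uncorrelated extra points;
convolution with a unit-sum anisotropic Gaussian PSF parameterized by
lateral/axial FWHM (truncated at 4σ, renormalized; a warning fires below
2.5 voxels per FWHM, the Nyquist guidance for sampling a PSF); then flat
background, then additive Gaussian noise (modeling camera dark/readout
noise), then optional zero-clipping to emulate unsigned formats.

What it does **not** model: acquired-PSF side lobes, aberrations and the
noise baked into measured PSF kernels; shot noise (no Poisson option);
sub-voxel emitter positions; intensity heterogeneity between emitters.
Passing tests on these scenes therefore validate the algorithmic chain
and its trend behavior, not absolute statistic values on real data.

Signal-to-background and signal-to-noise ratios are defined against the
*peak rendered point intensity* (the brightest voxel of the clean
convolved image), the natural reading for point sources.

### Scale dependence of noise effects

Noise enters the correlation volume as `sd²·√N_voxels` (the accumulated
noise-noise product over the field), while the per-pair correlation signal
is independent of the field size. Consequently the signal-to-noise ratio
at which fit quality collapses is not transferable between field sizes:
a ~30–60× smaller field tolerates roughly 2× more relative noise before
R² degrades. The test suite therefore demonstrates the noise phenomenology
(R² falls monotonically with noise while µ holds; extreme noise breaks the
fit; zero-clipped noise acts like added background and collapses
confidence) at ratios appropriate to its reduced scene sizes. The same
`√N` argument applies to the confidence penalty of flat background, which
is why the background and zero-bound checks also use desk-scale ratios.

### Problem sizes used by the test suite

Chosen to exercise the full 3-D chain at laptop-scale cost: oracle
equivalence on ≤ 10³-voxel volumes against direct-sum references;
zero-distance recovery on 128×128×32 scenes (10 seeds); distance recovery
(50 pairs at 1.13 µm, 75.4 nm voxels, 0.3 µm FWHM) on 160×160×64 scenes
with 5 replicates; degradation trends on 96×96×32 scenes (25 pairs) and
160×160×48 (noise, 30 pairs, Nyquist-limit 0.19 µm FWHM). The replicate
protocol (mean ± SD over independently generated scenes, fit failures
excluded and counted) mirrors the reference evaluation at n = 10.

## Known limitations

* Single-Gaussian model; no multi-peak fitting.
* One-sided randomization (the first image only); sequential dual
  randomization would be more robust for channels with very different
  spatial statistics.
* Confidence thresholds are empirical; ~0.1 suggests a reasonably likely
  and ~0.2 a very likely true correlation on typical biological data.
* Recovered µ carries a small systematic underestimate (a few percent of
  the true distance) inherent to fitting the radially averaged,
  discretely binned correlation of blurred pairs; report µ together
  with σ.
* Whole volumes are processed in memory; no tiling or GPU path.
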