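"""Independent brute-force reference implementations used by the tests.

Everything here is written as direct sums/loops over definitions, kept
deliberately separate from the FFT/vectorized code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_cross_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """result(s) = sum_x a(x) * b(x + s), zero padding, center = shape//2."""
    shape = a.shape
    center = tuple(n // 2 for n in shape)
    out = np.zeros(shape)
    for idx in np.ndindex(*shape):
        s = tuple(i - c for i, c in zip(idx, center))
        total = 0.0
        for x in np.ndindex(*shape):
            y = tuple(xi + si for xi, si in zip(x, s))
            if all(0 <= yi < n for yi, n in zip(y, shape)):
                total += a[x] * b[y]
        out[idx] = total
    return out


def brute_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """out(i) = sum_j img(i + c - j) * kernel(j), c = kernel shape//2."""
    c = tuple(k // 2 for k in kernel.shape)
    out = np.zeros(img.shape)
    for i in np.ndindex(*img.shape):
        total = 0.0
        for j in np.ndindex(*kernel.shape):
            x = tuple(ii + ci - ji for ii, ci, ji in zip(i, c, j))
            if all(0 <= xi < n for xi, n in zip(x, img.shape)):
                total += img[x] * kernel[j]
        out[i] = total
    return out


def brute_correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """out(i) = sum_j img(i - c + j) * kernel(j), c = kernel shape//2."""
    c = tuple(k // 2 for k in kernel.shape)
    out = np.zeros(img.shape)
    for i in np.ndindex(*img.shape):
        total = 0.0
        for j in np.ndindex(*kernel.shape):
            x = tuple(ii - ci + ji for ii, ci, ji in zip(i, c, j))
            if all(0 <= xi < n for xi, n in zip(x, img.shape)):
                total += img[x] * kernel[j]
        out[i] = total
    return out


def brute_radial_profile(
    data: np.ndarray, center: tuple[int, ...], scale: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance-sort-and-average reference binning (nearest bin center)."""
    bin_width = min(scale)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for idx in np.ndindex(*data.shape):
        d = np.sqrt(
            sum(((i - c) * s) ** 2 for i, c, s in zip(idx, center, scale))
        )
        k = int(round(d / bin_width))
        sums[k] = sums.get(k, 0.0) + data[idx]
        counts[k] = counts.get(k, 0) + 1
    n_bins = max(counts) + 1
    values = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=int)
    for k in counts:
        cnt[k] = counts[k]
        values[k] = sums[k] / counts[k]
    centers = np.arange(n_bins) * bin_width
    return centers, values, cnt


def brute_otsu(values: np.ndarray) -> float:
    """Exhaustive threshold search maximizing between-class variance.

    Every split between consecutive distinct data values is tried, so the
    returned threshold is the global maximizer over all possible masks.
    """
    flat = np.sort(values.ravel())
    candidates = (np.unique(flat)[:-1] + np.unique(flat)[1:]) / 2.0
    best_t, best_var = candidates[0], -np.inf
    for t in candidates:
        low = flat[flat <= t]
        high = flat[flat > t]
        w0 = len(low) / len(flat)
        w1 = 1.0 - w0
        var = w0 * w1 * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def brute_gaussian_modify(
    data: np.ndarray,
    center: tuple[int, ...],
    scale: tuple[float, ...],
    mu: float,
    sigma: float,
) -> np.ndarray:
    """Per-voxel distance / multiply loop."""
    out = np.zeros(data.shape)
    for idx in np.ndindex(*data.shape):
        d = np.sqrt(
            sum(((i - c) * s) ** 2 for i, c, s in zip(idx, center, scale))
        )
        out[idx] = data[idx] * np.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
    return out
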