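"""Contact-matrix smoothing: low-rank completion, mean filter, Gaussian filter.

The factorization-based smoother reconstructs X^s = U V^T from fitted
non-negative factors, imputing unobserved (zero) entries from the low-rank
structure.  The mean and Gaussian filters are classical image-blurring
baselines operating on a square window around each entry; windows are
truncated at the matrix edges and renormalized by the in-bounds weight mass,
so a constant matrix is preserved exactly everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

from .graph_nmf import FactorPair


def smooth_completion(f: FactorPair) -> np.ndarray:
    """Smoothed matrix from the factor product, symmetrized: (UV^T + VU^T)/2.

    For a symmetric input U and V agree up to scaling, but not exactly, so
    the product is symmetrized to keep the contact-matrix invariants.
    """
    P = f.U @ f.V.T
    return (P + P.T) / 2.0


def _window_normalized(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    num = correlate(X, kernel, mode="constant", cval=0.0)
    den = correlate(np.ones_like(X), kernel, mode="constant", cval=0.0)
    return num / den


def mean_filter(X: np.ndarray, radius_bins: int) -> np.ndarray:
    """Average over the (2r+1)^2 window around each entry.

    Edge windows are truncated: the denominator is the number of in-bounds
    cells, not (2r+1)^2.
    """
    if radius_bins < 1:
        raise ValueError(f"radius must be >= 1, got {radius_bins}")
    X = np.asarray(X, dtype=float)
    size = 2 * radius_bins + 1
    return _window_normalized(X, np.ones((size, size)))


def gaussian_filter(X: np.ndarray, sigma: float, normalize: bool = True) -> np.ndarray:
    """Gaussian-weighted mean over a window of half-width 4*sigma.

    Weights are exp(-((i-a)^2 + (j-b)^2) / (2 sigma^2)).  With
    ``normalize=True`` (default) the output divides by the in-bounds weight
    sum, preserving constants and avoiding edge damping; ``normalize=False``
    applies the analytic prefactor 1/(2 pi sigma^2) instead.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    X = np.asarray(X, dtype=float)
    half = int(4 * sigma)
    ax = np.arange(-half, half + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    if normalize:
        return _window_normalized(X, kernel)
    num = correlate(X, kernel, mode="constant", cval=0.0)
    return num / (2.0 * np.pi * sigma**2)
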