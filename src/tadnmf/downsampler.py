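"""Distance-stratified downsampling of a deep contact matrix.

Hi-C counts decay strongly with genomic distance, so depth reduction must be
matched stratum by stratum: for each distance d (in bins, diagonal = 0),
enough non-zero entries of the deep matrix are zeroed (uniformly at random,
symmetrically) to match the target's zero count at d, and the surviving
entries are scaled so their mean matches the target's non-zero mean at d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DistanceProfile:
    """Per-distance summary of the upper triangle (diagonal included, d=0).

    Arrays are indexed by distance d = 0 .. n_bins-1; at each d,
    ``n_nonzero[d] + n_zero[d]`` equals the number of upper-triangle pairs at
    that distance and ``mean_nonzero[d]`` is the mean of the non-zero counts
    (0 where there are none).
    """

    mean_nonzero: np.ndarray
    n_nonzero: np.ndarray
    n_zero: np.ndarray

    @property
    def n_distances(self) -> int:
        return len(self.mean_nonzero)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": np.arange(self.n_distances),
                "mean_nonzero": self.mean_nonzero,
                "n_nonzero": self.n_nonzero,
                "n_zero": self.n_zero,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "DistanceProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            mean_nonzero=df["mean_nonzero"].to_numpy(float),
            n_nonzero=df["n_nonzero"].to_numpy(int),
            n_zero=df["n_zero"].to_numpy(int),
        )


def distance_profile(X: np.ndarray) -> DistanceProfile:
    """Stratify the upper triangle of X by |i - j| and summarize each stratum."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mean_nz = np.zeros(n)
    n_nz = np.zeros(n, dtype=int)
    n_z = np.zeros(n, dtype=int)
    for d in range(n):
        diag = np.diagonal(X, offset=d)
        nz = diag != 0
        n_nz[d] = int(nz.sum())
        n_z[d] = len(diag) - n_nz[d]
        if n_nz[d]:
            mean_nz[d] = diag[nz].mean()
    return DistanceProfile(mean_nonzero=mean_nz, n_nonzero=n_nz, n_zero=n_z)


def scale_profile(
    profile: DistanceProfile, mean_factor: float, zero_factor: float
) -> DistanceProfile:
    """Derive a shallower target: means scaled by ``mean_factor``, zero counts
    scaled by ``zero_factor`` (capped at the stratum size)."""
    total = profile.n_nonzero + profile.n_zero
    n_zero = np.minimum(np.round(profile.n_zero * zero_factor).astype(int), total)
    return DistanceProfile(
        mean_nonzero=profile.mean_nonzero * mean_factor,
        n_nonzero=total - n_zero,
        n_zero=n_zero,
    )


def downsample(
    X_high: np.ndarray, target: DistanceProfile, seed: int = 0
) -> np.ndarray:
    """Downsample ``X_high`` so its per-distance non-zero means and zero counts
    match ``target``.

    At each distance d, z_d = max(0, target zeros - existing zeros) non-zero
    entries are zeroed uniformly at random (mirrored into the lower triangle),
    and the surviving entries are rescaled by the ratio of their own mean to
    the target mean mu_d^l, so the realized non-zero mean matches the target
    exactly rather than only in expectation.  Scaled values stay real-valued;
    no re-rounding to integer counts.
    """
    X = np.asarray(X_high, dtype=float)
    n = X.shape[0]
    if target.n_distances < n:
        raise ValueError(
            f"target profile covers {target.n_distances} distances; matrix needs {n}"
        )
    high = distance_profile(X)
    rng = np.random.default_rng(seed)
    out = X.copy()
    for d in range(n):
        idx = np.arange(n - d)
        rows, cols = idx, idx + d
        vals = out[rows, cols]
        nz = vals != 0
        if target.mean_nonzero[d] > 0 and high.mean_nonzero[d] == 0:
            warnings.warn(
                f"distance {d}: target mean requested but no non-zero entries; skipped"
            )
            continue
        z_d = max(0, int(target.n_zero[d]) - int(high.n_zero[d]))
        nz_pos = np.nonzero(nz)[0]
        if z_d > 0 and len(nz_pos):
            kill = rng.choice(nz_pos, size=min(z_d, len(nz_pos)), replace=False)
            vals[kill] = 0.0
        survivors = vals != 0
        if survivors.any() and target.mean_nonzero[d] > 0:
            vals[survivors] /= vals[survivors].mean() / target.mean_nonzero[d]
        out[rows, cols] = vals
        out[cols, rows] = vals
    return out
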