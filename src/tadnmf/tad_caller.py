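"""Chain-constrained k-medoids: contiguous clusters (TADs) from factor rows.

Ordinary k-medoids on the rows of the factor matrix U can scatter a cluster
across the chromosome.  The chain-constrained variant forces every cluster to
be one consecutive run of bins: medoids start evenly spaced along the chain,
each pair of consecutive medoids competes for the bins between them via a
single optimal split point, and medoids are then re-centered within their
runs.  The result is a genomic segmentation whose segments are the TADs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .matrix_io import TADInterval


@dataclass
class ClusterAssignment:
    """Per-bin integer labels forming contiguous runs, relabeled 0..m-1 in order."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        runs = run_lengths(self.labels)
        # label -1 is reserved for background (non-TAD) stretches and may recur
        ids = [lab for lab, _ in runs if lab >= 0]
        if len(set(ids)) != len(ids):
            raise ValueError("labels are not contiguous: a cluster id recurs in two runs")

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, run length) for each maximal consecutive run."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    change = np.nonzero(np.diff(labels))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(labels) - 1]))
    return [(int(labels[s]), int(e - s + 1)) for s, e in zip(starts, ends)]


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel contiguous runs as 0..m-1 in genomic order."""
    labels = np.asarray(labels)
    out = np.empty_like(labels)
    nxt = 0
    prev = None
    for idx, lab in enumerate(labels):
        if prev is None or lab != prev:
            cur = nxt
            nxt += 1
            prev = lab
        out[idx] = cur
    return out


class ChainKMedoids(ClusterMixin, BaseEstimator):
    """k-medoids clustering constrained to consecutive runs along a chain.

    Parameters
    ----------
    n_clusters : int
        Number of clusters requested; the fitted count can be smaller if
        medoids collapse onto the same bin.
    max_iter : int, default=50

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Contiguous integer labels, canonically 0..m-1 left to right.
    medoids_ : ndarray
        Bin index of each cluster's medoid.
    inertia_ : float
        Total distance of rows to their cluster medoid.
    n_iter_ : int

    Notes
    -----
    Distances are Euclidean on the feature rows.  Initialization is
    deterministic (medoid t starts at bin floor((2t+1) n / 2k)) and all ties
    break toward the smaller bin index, so repeated fits are identical.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 50):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        k = self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds number of bins {n}")
        if not np.isfinite(X).all():
            raise ValueError("feature matrix contains NaN/Inf")

        medoids = np.unique([(2 * t + 1) * n // (2 * k) for t in range(k)])
        if len(medoids) < k:
            warnings.warn(
                f"medoid initialization collapsed {k - len(medoids)} duplicate "
                f"medoids; returning {len(medoids)} clusters"
            )
        labels = self._assign(X, medoids)
        costs = [self._cost(X, labels, medoids)]
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            n_iter = it
            new_medoids = self._update_medoids(X, labels, len(medoids))
            new_medoids = np.unique(new_medoids)
            if len(new_medoids) < len(medoids):
                warnings.warn("medoids collapsed during update; merging clusters")
            new_labels = self._assign(X, new_medoids)
            medoids = new_medoids
            costs.append(self._cost(X, new_labels, medoids))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        self.cost_trajectory_ = costs

        self.labels_ = canonical_labels(labels)
        self.medoids_ = medoids
        self.inertia_ = costs[-1]
        self.n_iter_ = n_iter
        return self

    @staticmethod
    def _cost(X: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
        return float(
            sum(
                np.linalg.norm(X[labels == c] - X[m], axis=1).sum()
                for c, m in enumerate(medoids)
            )
        )

    @staticmethod
    def _assign(X: np.ndarray, medoids: np.ndarray) -> np.ndarray:
        """Optimal single-split assignment between consecutive medoids."""
        n = X.shape[0]
        labels = np.empty(n, dtype=int)
        labels[: medoids[0] + 1] = 0
        labels[medoids[-1] :] = len(medoids) - 1
        for t in range(len(medoids) - 1):
            a, b = medoids[t], medoids[t + 1]
            # bins a..b are split: a..s -> cluster t, s+1..b -> cluster t+1
            seg = X[a : b + 1]
            d_left = np.linalg.norm(seg - X[a], axis=1)
            d_right = np.linalg.norm(seg - X[b], axis=1)
            left_cost = np.concatenate(([0.0], np.cumsum(d_left[:-1])))
            right_cost = np.concatenate((np.cumsum(d_right[::-1])[::-1][1:], [0.0]))
            # cost(s) = sum d_left[a..s] + sum d_right[s+1..b], s in [a, b-1]
            costs = left_cost[1:] + right_cost[:-1]
            s = a + int(np.argmin(costs))
            labels[a : s + 1] = t
            labels[s + 1 : b + 1] = t + 1
        return labels

    @staticmethod
    def _update_medoids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
        medoids = np.empty(k, dtype=int)
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            sub = X[members]
            # pairwise distance totals; cluster sizes are small enough for O(m^2)
            diff = sub[:, None, :] - sub[None, :, :]
            totals = np.sqrt((diff * diff).sum(axis=2)).sum(axis=1)
            medoids[c] = members[int(np.argmin(totals))]
        return medoids


def chain_kmedoids(
    U: np.ndarray, k_clusters: int, max_iter: int = 50, seed: int | None = None
) -> ClusterAssignment:
    """Cluster factor rows into contiguous runs (seed accepted but unused:
    initialization and tie-breaking are deterministic)."""
    est = ChainKMedoids(n_clusters=k_clusters, max_iter=max_iter).fit(U)
    return ClusterAssignment(labels=est.labels_)


def clusters_to_tads(
    a: ClusterAssignment, meta: tuple[str, int, int] = ("chr1", 1, 0)
) -> list[TADInterval]:
    """One TADInterval per label run, ordered along the chromosome."""
    chrom = meta[0]
    tads = []
    pos = 0
    for lab, length in run_lengths(a.labels):
        tads.append(TADInterval(chrom, pos, pos + length - 1, lab))
        pos += length
    return tads


def tad_boundaries(tads: list[TADInterval], n_bins: int) -> set[int]:
    """Boundary bins: each TAD's first and last bin plus one flank on each side,
    clipped to the chromosome and deduplicated."""
    out: set[int] = set()
    for t in tads:
        for b in (t.start_bin - 1, t.start_bin, t.end_bin, t.end_bin + 1):
            if 0 <= b < n_bins:
                out.add(b)
    return out
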