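"""TAD-quality, stability, enrichment and overlap metrics.

Internal cluster-quality scores (Davies-Bouldin index, delta contact count)
are computed per TAD and compared against empirical nulls built by shuffling
the TAD/non-TAD stretch order along the chromosome, which preserves the TAD
length distribution.  Clustering agreement uses the Rand index and the
plug-in mutual information; boundary enrichment uses fold enrichment over the
chromosome-wide binding rate and an upper-tail hypergeometric test; recovery
of scored interaction sets uses Jaccard overlap and the area under the
precision-recall curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import average_precision_score, mutual_info_score, rand_score

from .matrix_io import BinAnnotation
from .tad_caller import ClusterAssignment, run_lengths

# Reserved label for genome stretches a TAD caller skipped; such stretches form
# one shared background cluster in comparisons and are excluded from per-TAD
# statistics.
BACKGROUND = -1


@dataclass
class NullDistribution:
    """Values of one statistic over shuffled-TAD replicates."""

    statistic: str
    values: np.ndarray
    direction: str  # "lower_is_better" | "higher_is_better"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0 or not np.isfinite(self.values).all():
            raise ValueError("null distribution must be non-empty and finite")
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _cluster_members(a: ClusterAssignment) -> dict[int, np.ndarray]:
    return {
        int(c): np.nonzero(a.labels == c)[0]
        for c in np.unique(a.labels)
        if c != BACKGROUND
    }


def dbi_per_cluster(X: np.ndarray, a: ClusterAssignment) -> dict[int, float]:
    """Per-cluster Davies-Bouldin index over full matrix rows; lower is better.

    DBI_i = max_{j != i} (d_i + d_j) / dist(centroid_i, centroid_j) with d_i
    the mean Euclidean distance of member rows to their cluster centroid.
    """
    X = np.asarray(X, dtype=float)
    members = _cluster_members(a)
    if len(members) < 2:
        raise ValueError("DBI needs at least 2 clusters")
    ids = sorted(members)
    centroids = {c: X[members[c]].mean(axis=0) for c in ids}
    scatter = {
        c: float(np.linalg.norm(X[members[c]] - centroids[c], axis=1).mean())
        for c in ids
    }
    out: dict[int, float] = {}
    for ci in ids:
        best = -np.inf
        for cj in ids:
            if cj == ci:
                continue
            dist = float(np.linalg.norm(centroids[ci] - centroids[cj]))
            if dist == 0:
                warnings.warn(f"coincident centroids for clusters {ci}, {cj}")
                s = np.inf
            else:
                s = (scatter[ci] + scatter[cj]) / dist
            best = max(best, s)
        out[ci] = best
    return out


def dcc_per_cluster(X: np.ndarray, a: ClusterAssignment) -> dict[int, float]:
    """Delta contact count: mean within-cluster pair count minus mean count of
    pairs straddling the cluster boundary; higher is better.  Diagonal
    entries are excluded (pairs p < q).  Singleton clusters are skipped with
    a warning (their within mean is undefined)."""
    X = np.asarray(X, dtype=float)
    members = _cluster_members(a)
    n = X.shape[0]
    out: dict[int, float] = {}
    for c, m in sorted(members.items()):
        if len(m) < 2:
            warnings.warn(f"cluster {c} is a singleton; DCC undefined, skipped")
            continue
        inside = X[np.ix_(m, m)]
        iu = np.triu_indices(len(m), k=1)
        in_mean = float(inside[iu].mean())
        others = np.setdiff1d(np.arange(n), m)
        if len(others) == 0:
            warnings.warn(f"cluster {c} covers the whole chromosome; DCC skipped")
            continue
        out_mean = float(X[np.ix_(m, others)].mean())
        out[c] = in_mean - out_mean
    return out


def shuffle_tads(
    a: ClusterAssignment, n_shuffles: int = 10, seed: int = 0
) -> list[ClusterAssignment]:
    """Shuffled-TAD null assignments: permute the order of TAD and non-TAD
    stretches along the chromosome, preserving both length multisets."""
    rng = np.random.default_rng(seed)
    runs = run_lengths(a.labels)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(runs))
        labels = np.concatenate(
            [np.full(runs[p][1], runs[p][0], dtype=int) for p in perm]
        )
        # after permutation, distinct TAD runs keep distinct ids; re-key
        # non-background runs canonically while preserving the background label
        relabeled = np.empty_like(labels)
        nxt = 0
        pos = 0
        for p in perm:
            lab, length = runs[p]
            if lab == BACKGROUND:
                relabeled[pos : pos + length] = BACKGROUND
            else:
                relabeled[pos : pos + length] = nxt
                nxt += 1
            pos += length
        out.append(ClusterAssignment(labels=relabeled))
    return out


def empirical_significance(
    observed: np.ndarray, null: NullDistribution, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Empirical per-TAD p-values against a shuffled-TAD null.

    p = fraction of null values strictly better than the observed value
    (direction-aware; ties count as not better).  Returns the p-values and
    the fraction of TADs with p < alpha.
    """
    observed = np.asarray(observed, dtype=float)
    nv = null.values
    if null.direction == "higher_is_better":
        p = (nv[None, :] > observed[:, None]).mean(axis=1)
    else:
        p = (nv[None, :] < observed[:, None]).mean(axis=1)
    return p, float((p < alpha).mean())


def mean_signal_per_tad(signal: np.ndarray, a: ClusterAssignment) -> dict[int, float]:
    """Mean of a per-bin signal track within each TAD."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) != a.n_bins:
        raise ValueError(
            f"track length {len(signal)} != n_bins {a.n_bins}"
        )
    return {
        c: float(signal[m].mean()) for c, m in sorted(_cluster_members(a).items())
    }


def rand_index(A, B) -> float:
    """Rand index: fraction of bin pairs on which two clusterings agree
    (co-clustered in both or separated in both); 1 = identical partitions."""
    A, B = np.asarray(A), np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"label length mismatch: {A.shape} vs {B.shape}")
    return float(rand_score(A, B))


def mutual_information(A, B) -> float:
    """Plug-in mutual information (natural log) between two labelings."""
    A, B = np.asarray(A), np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"label length mismatch: {A.shape} vs {B.shape}")
    return float(mutual_info_score(A, B))


def refine_labels(labels, factor: int) -> np.ndarray:
    """Repeat each bin's label ``factor`` times (coarse bins split into
    constituent fine bins, e.g. 25 kb -> 5 kb uses factor 5)."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"refinement factor must be a positive integer, got {factor}")
    return np.repeat(np.asarray(labels), int(factor))


def fold_enrichment(boundaries: set[int], ann: BinAnnotation) -> float:
    """(n_TAD-BIND / n_TAD) / (n_BIND / N): binding rate in boundary bins over
    the chromosome-wide binding rate."""
    N = ann.n_bins
    n_tad = len(boundaries)
    n_bind = int(ann.indicator.sum())
    if n_tad == 0 or n_bind == 0:
        raise ValueError("fold enrichment undefined: no boundaries or no binding bins")
    n_tad_bind = int(ann.indicator[sorted(boundaries)].sum())
    return (n_tad_bind / n_tad) / (n_bind / N)


def hypergeom_enrichment(
    counts: tuple[int, int, int, int] | None = None,
    *,
    boundaries: set[int] | None = None,
    ann: BinAnnotation | None = None,
) -> float:
    """Upper-tail hypergeometric p-value P[X >= n_TAD-BIND].

    Either pass aggregated ``counts`` = (N, n_BIND, n_TAD, n_TAD-BIND) — e.g.
    summed across chromosomes — or ``boundaries`` and ``ann`` for a single
    chromosome.
    """
    if counts is None:
        if boundaries is None or ann is None:
            raise ValueError("need either counts or (boundaries, ann)")
        counts = (
            ann.n_bins,
            int(ann.indicator.sum()),
            len(boundaries),
            int(ann.indicator[sorted(boundaries)].sum()),
        )
    N, n_bind, n_tad, n_tad_bind = counts
    if n_tad == 0 or n_bind == 0:
        raise ValueError("hypergeometric enrichment undefined for empty margins")
    return float(hypergeom.sf(n_tad_bind - 1, N, n_bind, n_tad))


def aggregate_hypergeom(per_chrom: list[tuple[int, int, int, int]]) -> float:
    """Hypergeometric enrichment with counts summed across chromosomes."""
    totals = tuple(int(sum(c[i] for c in per_chrom)) for i in range(4))
    return hypergeom_enrichment(totals)


def jaccard(setA, setB) -> float:
    """|A intersect B| / |A union B|; 0 (with warning) when both are empty."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        warnings.warn("Jaccard of two empty sets; returning 0")
        return 0.0
    return len(A & B) / len(union)


def aupr(truth: set[tuple[int, int]], predictions) -> float:
    """Area under the precision-recall curve for recovering ``truth`` pairs
    from scored predictions (iterable of (i, j, score)); the prediction
    universe defines the evaluation domain and must cover the truth set."""
    preds = {(min(i, j), max(i, j)): float(s) for i, j, s in predictions}
    truth = {(min(i, j), max(i, j)) for i, j in truth}
    if not truth:
        raise ValueError("truth set is empty")
    missing = truth - set(preds)
    if missing:
        raise ValueError(f"{len(missing)} truth pairs absent from prediction universe")
    pairs = sorted(preds)
    y_true = np.array([p in truth for p in pairs], dtype=int)
    y_score = np.array([preds[p] for p in pairs])
    return float(average_precision_score(y_true, y_score))


def match_clusters_across_conditions(
    A: ClusterAssignment,
    B: ClusterAssignment,
    j_min: float = 0.2,
    split_min: int = 2,
) -> list[tuple[int, list[tuple[int, float]]]]:
    """Clusters of A matching >= ``split_min`` clusters of B at Jaccard >=
    ``j_min`` — candidate split/merge sites between two conditions."""
    if A.n_bins != B.n_bins:
        raise ValueError("assignments cover different numbers of bins")
    membersA = _cluster_members(A)
    membersB = {c: set(m.tolist()) for c, m in _cluster_members(B).items()}
    flagged = []
    for ca, ma in sorted(membersA.items()):
        sa = set(ma.tolist())
        matches = [
            (cb, jaccard(sa, mb))
            for cb, mb in sorted(membersB.items())
            if jaccard(sa, mb) >= j_min
        ]
        if len(matches) >= split_min:
            flagged.append((ca, matches))
    return flagged
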