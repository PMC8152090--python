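"""End-to-end TAD calling: factorize, cluster contiguously, reconstruct.

``TADCaller`` composes :class:`~tadnmf.graph_nmf.GraphRegularizedNMF` with
:class:`~tadnmf.tad_caller.ChainKMedoids`: the regularized factors give each
bin a smooth latent profile, the chain-constrained clustering segments the
chromosome into contiguous domains, and the symmetrized factor product is the
smoothed (imputed) contact matrix — one fit yields TADs and smoothing
together.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .graph_nmf import FactorPair, GraphRegularizedNMF, choose_k
from .matrix_io import ContactMatrix, TADInterval
from .smoother import smooth_completion
from .tad_caller import ChainKMedoids, ClusterAssignment, clusters_to_tads


class TADCaller(ClusterMixin, BaseEstimator):
    """Call contiguous TADs from a symmetric contact matrix.

    Parameters
    ----------
    n_clusters : int or None
        Number of domains k; when None it is derived from
        ``expected_tad_size`` and the matrix metadata at fit time.
    expected_tad_size : int, default=1_000_000
        Expected domain span in bp used to derive k (1 Mb = TAD scale).
    radius : int, default=250_000
        Graph-regularization neighborhood radius in bp.
    lam : float, default=1.0
        Regularization strength.
    bin_size : int, default=25_000
        Bin width in bp; used to convert bp-valued settings into bins when
        fitting a bare array (a ContactMatrix carries its own).
    max_iter, tol, check_every, random_state
        Passed to the factorization; ``kmedoids_max_iter`` to the clustering.

    Attributes
    ----------
    labels_ : ndarray
        Contiguous per-bin cluster labels.
    tads_ : list of TADInterval
    factors_ : FactorPair
    smoothed_ : ndarray
        Symmetrized low-rank reconstruction of the input.
    n_clusters_ : int
        The rank/cluster count actually used.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        expected_tad_size: int = 1_000_000,
        radius: int = 250_000,
        lam: float = 1.0,
        bin_size: int = 25_000,
        max_iter: int = 300,
        tol: float = 1e-4,
        check_every: int = 10,
        kmedoids_max_iter: int = 50,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.expected_tad_size = expected_tad_size
        self.radius = radius
        self.lam = lam
        self.bin_size = bin_size
        self.max_iter = max_iter
        self.tol = tol
        self.check_every = check_every
        self.kmedoids_max_iter = kmedoids_max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, ContactMatrix):
            counts, bin_size, chrom = X.counts, X.bin_size, X.chrom
        else:
            counts = np.asarray(X, dtype=float)
            bin_size, chrom = self.bin_size, "chr1"
        n = counts.shape[0]
        k = self.n_clusters or choose_k(n, bin_size, self.expected_tad_size)
        if self.radius < bin_size:
            raise ValueError(f"radius {self.radius} bp < bin size {bin_size} bp")

        nmf = GraphRegularizedNMF(
            n_components=k,
            radius_bins=int(self.radius // bin_size),
            lam=self.lam,
            max_iter=self.max_iter,
            tol=self.tol,
            check_every=self.check_every,
            random_state=self.random_state,
        ).fit(counts)
        km = ChainKMedoids(n_clusters=k, max_iter=self.kmedoids_max_iter).fit(nmf.U_)

        self.nmf_ = nmf
        self.factors_ = FactorPair(
            U=nmf.U_, V=nmf.V_, final_objective=nmf.objective_, n_iter_run=nmf.n_iter_
        )
        self.labels_ = km.labels_
        self.assignment_ = ClusterAssignment(labels=km.labels_)
        self.tads_ = clusters_to_tads(self.assignment_, (chrom, bin_size, 0))
        self.smoothed_ = smooth_completion(self.factors_)
        self.n_clusters_ = k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def call_tads(
    matrix: ContactMatrix,
    n_clusters: int | None = None,
    expected_tad_size: int = 1_000_000,
    radius: int = 250_000,
    lam: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> tuple[list[TADInterval], ClusterAssignment, FactorPair, np.ndarray]:
    """One-shot pipeline: returns (tads, assignment, factors, smoothed)."""
    est = TADCaller(
        n_clusters=n_clusters,
        expected_tad_size=expected_tad_size,
        radius=radius,
        lam=lam,
        random_state=seed,
        **kwargs,
    ).fit(matrix)
    return est.tads_, est.assignment_, est.factors_, est.smoothed_
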