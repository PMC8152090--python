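"""Chain neighbor graph and graph-regularized non-negative matrix factorization.

The factorization minimizes

    ||X - U V^T||_F^2  +  lambda * Tr(V^T L V)  +  lambda * Tr(U^T L U)

over non-negative U, V (n x k), where L = D - W is the Laplacian of a
chain-neighborhood graph over the bins: W_ij = 1 iff 0 < |i - j| <= r bins.
The Laplacian terms penalize differences between the latent features of
linearly adjacent bins, so the learned factors vary smoothly along the
chromosome.  Optimization is by multiplicative updates

    U <- U * (X V + lam W U) / (U V^T V + lam D U + eps)
    V <- V * (X^T U + lam W V) / (V U^T U + lam D V + eps)

from a non-negative double-SVD (NNDSVD) initialization built on randomized
SVD, which makes the fit deterministic given a seed.  With lambda = 0 the
updates reduce to the classic unregularized multiplicative update rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd as _sk_randomized_svd

EPS = 1e-10


@dataclass(frozen=True)
class NeighborGraph:
    """Binary chain-adjacency graph over bins with degree and Laplacian."""

    n_bins: int
    r_bins: int
    W: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix


@dataclass
class Params:
    """Hyperparameters of the regularized factorization.

    Attributes
    ----------
    k : int or None
        Factorization rank = number of clusters.  When None it is derived
        from ``expected_tad_size`` via :func:`choose_k`.
    r : int
        Neighborhood radius in bp (default 250 kb).
    lam : float
        Regularization strength lambda >= 0 (default 1).
    expected_tad_size : int
        Expected domain size in bp used to derive k (default 1 Mb).
    max_iter, tol, check_every
        Stopping rule: iterate until the relative objective decrease over
        ``check_every`` iterations falls below ``tol`` or ``max_iter`` is hit.
    seed : int
        Seed for the randomized SVD behind the initialization.
    """

    k: int | None = None
    r: int = 250_000
    lam: float = 1.0
    expected_tad_size: int = 1_000_000
    max_iter: int = 300
    tol: float = 1e-4
    check_every: int = 10
    seed: int = 0


@dataclass
class FactorPair:
    """Fitted non-negative factors and fit diagnostics."""

    U: np.ndarray
    V: np.ndarray
    final_objective: float
    n_iter_run: int


def choose_k(n_bins: int, bin_size: int, expected_tad_size: int) -> int:
    """Rank k such that the expected cluster spans ``expected_tad_size`` bp.

    k = max(2, round(chromosome_length / expected_tad_size)).
    """
    if expected_tad_size < bin_size:
        raise ValueError(
            f"expected_tad_size ({expected_tad_size}) < bin_size ({bin_size})"
        )
    return max(2, round(n_bins * bin_size / expected_tad_size))


def build_neighbor_graph(n_bins: int, bin_size: int, r_bp: int) -> NeighborGraph:
    """Chain graph connecting bins within ``r_bp`` bp (r_bins = floor(r/bin))."""
    if r_bp < bin_size:
        raise ValueError(f"radius {r_bp} bp < bin_size {bin_size} bp: empty graph")
    r_bins = int(r_bp // bin_size)
    reach = min(r_bins, n_bins - 1)  # radius clipped by chromosome ends
    offsets = [o for o in range(-reach, reach + 1) if o != 0]
    W = sp.diags(
        [np.ones(n_bins - abs(o)) for o in offsets], offsets, format="csr"
    )
    deg = np.asarray(W.sum(axis=1)).ravel()
    D = sp.diags(deg, format="csr")
    L = (D - W).tocsr()
    return NeighborGraph(n_bins=n_bins, r_bins=r_bins, W=W, D=D, L=L)


def randomized_svd(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    oversample: int = 10,
    n_power_iter: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k approximate singular triplets (U, s, Vt), deterministic per seed."""
    X = np.asarray(X, dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} must be <= min(n, m)={min(X.shape)}")
    U, s, Vt = _sk_randomized_svd(
        X,
        n_components=k,
        n_oversamples=oversample,
        n_iter=n_power_iter,
        random_state=int(seed),
    )
    return U, s, Vt


def nndsvd_init(X: np.ndarray, k: int, seed: int = 0) -> FactorPair:
    """Non-negative double-SVD initialization (dense-fill variant).

    Column 0 is the scaled leading singular pair taken element-wise absolute;
    for each later component the sign-consistent positive/negative part pair
    with the larger norm product is kept and rescaled to preserve the singular
    value's energy.  Exact zeros are then replaced by ``mean(X)/100`` so that
    no entry is absorbing under the multiplicative updates.
    """
    X = np.asarray(X, dtype=float)
    if not X.any():
        raise ValueError("cannot initialize factors from an all-zero matrix")
    n, m = X.shape
    Us, s, Vt = randomized_svd(X, k, seed=seed)
    U = np.zeros((n, k))
    V = np.zeros((m, k))
    U[:, 0] = np.sqrt(s[0]) * np.abs(Us[:, 0])
    V[:, 0] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        x, y = Us[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        nxp, nyp = np.linalg.norm(xp), np.linalg.norm(yp)
        nxn, nyn = np.linalg.norm(xn), np.linalg.norm(yn)
        if nxp * nyp >= nxn * nyn:
            u, v, sigma = xp / max(nxp, EPS), yp / max(nyp, EPS), nxp * nyp
        else:
            u, v, sigma = xn / max(nxn, EPS), yn / max(nyn, EPS), nxn * nyn
        scale = np.sqrt(s[j] * sigma)
        U[:, j] = scale * u
        V[:, j] = scale * v
    fill = X.mean() / 100.0
    U[U == 0] = fill
    V[V == 0] = fill
    return FactorPair(U=U, V=V, final_objective=np.nan, n_iter_run=0)


def objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    L: sp.spmatrix | np.ndarray,
    lam: float,
) -> float:
    """Regularized reconstruction objective ||X-UV^T||_F^2 + lam(Tr V'LV + Tr U'LU)."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if U.shape[0] != n or V.shape[0] != m or U.shape[1] != V.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, U {U.shape}, V {V.shape}"
        )
    resid = X - U @ V.T
    val = float(np.sum(resid * resid))
    if lam != 0:
        val += lam * float(np.sum(V * (L @ V))) + lam * float(np.sum(U * (L @ U)))
    return val


class GraphRegularizedNMF(TransformerMixin, BaseEstimator):
    """Graph-regularized NMF of a symmetric contact matrix.

    scikit-learn style estimator: ``fit(X)`` factorizes the (n x n) count
    matrix; ``transform(X)`` returns the row-factor matrix ``U_``.

    Parameters
    ----------
    n_components : int
        Rank k of the factorization (also the number of clusters downstream).
    radius_bins : int, default=10
        Chain-graph neighborhood radius in bins (250 kb at 25 kb resolution).
    lam : float, default=1.0
        Regularization strength; 0 disables the Laplacian penalty.
    max_iter : int, default=300
    tol : float, default=1e-4
        Relative objective-decrease threshold evaluated every ``check_every``
        iterations.
    check_every : int, default=10
    random_state : int, default=0
        Seed for the randomized SVD used by the NNDSVD initialization.

    Attributes
    ----------
    U_, V_ : ndarray of shape (n, k)
        Fitted non-negative factors.
    objective_ : float
        Final value of the regularized objective.
    objective_trajectory_ : list of float
        Objective value at initialization and at each convergence check.
    n_iter_ : int
        Iterations actually run.
    """

    def __init__(
        self,
        n_components: int = 2,
        radius_bins: int = 10,
        lam: float = 1.0,
        max_iter: int = 300,
        tol: float = 1e-4,
        check_every: int = 10,
        random_state: int = 0,
        eps: float = EPS,
    ):
        self.n_components = n_components
        self.radius_bins = radius_bins
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.check_every = check_every
        self.random_state = random_state
        self.eps = eps

    def fit(self, X, y=None, U_init: np.ndarray | None = None, V_init: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if X.ndim != 2 or X.shape[1] != n:
            raise ValueError(f"X must be square, got {X.shape}")
        if not (2 <= self.n_components < n):
            raise ValueError(f"need 2 <= n_components < n_bins, got {self.n_components}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

        graph = build_neighbor_graph(n, 1, max(1, self.radius_bins))
        W, L = graph.W, graph.L
        deg = np.asarray(W.sum(axis=1)).ravel()

        if U_init is not None and V_init is not None:
            U = np.array(U_init, dtype=float)
            V = np.array(V_init, dtype=float)
        else:
            init = nndsvd_init(X, self.n_components, seed=self.random_state)
            U, V = init.U, init.V

        lam, eps = self.lam, self.eps
        obj = objective(X, U, V, L, lam)
        trajectory = [obj]
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            XV = X @ V
            if lam:
                XV += lam * (W @ U)
            denom = U @ (V.T @ V)
            if lam:
                denom += lam * (deg[:, None] * U)
            U = U * (XV / (denom + eps))

            XtU = X.T @ U
            if lam:
                XtU += lam * (W @ V)
            denom = V @ (U.T @ U)
            if lam:
                denom += lam * (deg[:, None] * V)
            V = V * (XtU / (denom + eps))

            n_iter = it
            if not (np.isfinite(U).all() and np.isfinite(V).all()):
                raise FloatingPointError(
                    f"non-finite factor values at iteration {it}"
                )
            if it % self.check_every == 0:
                new_obj = objective(X, U, V, L, lam)
                trajectory.append(new_obj)
                rel_drop = (obj - new_obj) / max(abs(obj), eps)
                obj = new_obj
                if rel_drop < self.tol:
                    break

        self.U_ = U
        self.V_ = V
        self.graph_ = graph
        self.objective_ = objective(X, U, V, L, lam)
        self.objective_trajectory_ = trajectory
        self.n_iter_ = n_iter
        return self

    def transform(self, X):
        """Return the fitted row factors U (latent features per bin)."""
        if not hasattr(self, "U_"):
            raise RuntimeError("estimator is not fitted")
        return self.U_

    def reconstruct(self) -> np.ndarray:
        """Symmetrized low-rank reconstruction (U V^T + V U^T) / 2."""
        if not hasattr(self, "U_"):
            raise RuntimeError("estimator is not fitted")
        P = self.U_ @ self.V_.T
        return (P + P.T) / 2.0


def fit(X: np.ndarray, params: Params, bin_size: int = 1) -> FactorPair:
    """Fit graph-regularized NMF with :class:`Params`; thin estimator wrapper.

    ``bin_size`` converts the bp-valued radius and expected TAD size into
    bins; pass bin_size=1 to interpret them as bin counts directly.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = params.k
    if k is None:
        k = choose_k(n, bin_size, params.expected_tad_size)
    if params.r < bin_size:
        raise ValueError(f"radius {params.r} bp < bin_size {bin_size} bp")
    est = GraphRegularizedNMF(
        n_components=k,
        radius_bins=int(params.r // bin_size),
        lam=params.lam,
        max_iter=params.max_iter,
        tol=params.tol,
        check_every=params.check_every,
        random_state=params.seed,
    ).fit(X)
    return FactorPair(
        U=est.U_, V=est.V_, final_objective=est.objective_, n_iter_run=est.n_iter_
    )
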