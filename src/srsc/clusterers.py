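"""Clustering back-ends: spatially constrained GMM plus K-means, FCM and GMM.

The constrained mixture model is a Gaussian mixture EM in which each voxel's
E-step responsibilities are multiplicatively weighted by the average
responsibilities of its 26-connected neighbors in image space from the
previous iteration (synchronous update), so a voxel is pulled toward the
tissue class of its spatial neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "NeighborGraph",
    "MixtureParams",
    "ResponsibilityField",
    "InitSpec",
    "KMeansResult",
    "FCMResult",
    "build_neighbor_graph",
    "neighbor_average",
    "make_init",
    "kmeans_fit",
    "fcm_fit",
    "fcm_memberships",
    "gmm_fit",
    "constrained_gmm_fit",
]

logger = logging.getLogger(__name__)

# offsets of the 26-connected neighborhood (Chebyshev distance 1)
_OFFSETS_26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


@dataclass
class NeighborGraph:
    """Adjacency of masked voxels under 26-connectivity, as a sparse matrix."""

    adjacency: scipy.sparse.csr_matrix
    coords: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    @classmethod
    def empty(cls, coords: np.ndarray) -> "NeighborGraph":
        n = len(coords)
        return cls(
            adjacency=scipy.sparse.csr_matrix((n, n)), coords=np.asarray(coords)
        )


def build_neighbor_graph(coords: np.ndarray, shape) -> NeighborGraph:
    """Link each masked voxel to its masked 26-connected grid neighbors."""
    coords = np.asarray(coords, dtype=int)
    shape = tuple(shape)
    n = len(coords)
    # flat index -> row lookup
    flat = np.ravel_multi_index(tuple(coords.T), shape)
    if len(np.unique(flat)) != n:
        raise ValueError("coords are not unique")
    lookup = -np.ones(int(np.prod(shape)), dtype=np.int64)
    lookup[flat] = np.arange(n)

    rows, cols = [], []
    for off in _OFFSETS_26:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        j = lookup[np.ravel_multi_index(tuple(shifted[ok].T), shape)]
        hit = j >= 0
        rows.append(np.flatnonzero(ok)[hit])
        cols.append(j[hit])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return NeighborGraph(adjacency=adj, coords=coords)


def neighbor_average(R: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Average the class probabilities of each voxel's masked neighbors.

    Voxels without masked neighbors get a uniform row 1/K (no spatial
    information).
    """
    R = np.asarray(R, dtype=float)
    K = R.shape[1]
    deg = graph.degrees
    S = graph.adjacency @ R
    has = deg > 0
    S[has] /= deg[has, None]
    S[~has] = 1.0 / K
    return S


# ---------------------------------------------------------------------------
# shared mixture-model machinery


@dataclass
class MixtureParams:
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclass
class ResponsibilityField:
    """Per-voxel class probabilities with the objective trace of the fit."""

    R: np.ndarray
    coords: np.ndarray | None = None
    trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


@dataclass
class InitSpec:
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    strategy: str
    seed: int


def _log_gaussians(Y: np.ndarray, params: MixtureParams) -> np.ndarray:
    """N x K matrix of log N(y_i | mu_k, Sigma_k) via Cholesky factors."""
    n, d = Y.shape
    out = np.empty((n, params.K))
    for k in range(params.K):
        chol = np.linalg.cholesky(params.covariances[k])
        diff = Y - params.means[k]
        sol = scipy.linalg.solve_triangular(chol, diff.T, lower=True)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _ridge_for(Y: np.ndarray) -> float:
    pooled_diag = Y.var(axis=0, ddof=1) if len(Y) > 1 else np.ones(Y.shape[1])
    eps = 1e-6 * float(np.mean(pooled_diag))
    return max(eps, 1e-12)


def _m_step(Y: np.ndarray, R: np.ndarray, ridge: float) -> MixtureParams:
    n, d = Y.shape
    nk = R.sum(axis=0)
    weights = nk / n
    means = (R.T @ Y) / nk[:, None]
    covs = np.empty((len(nk), d, d))
    for k in range(len(nk)):
        diff = Y - means[k]
        covs[k] = (R[:, k, None] * diff).T @ diff / nk[k]
        covs[k] = 0.5 * (covs[k] + covs[k].T) + ridge * np.eye(d)
    return MixtureParams(weights=weights, means=means, covariances=covs)


def _reseed_collapsed(
    Y: np.ndarray, R: np.ndarray, params: MixtureParams, collapsed: np.ndarray,
    ridge: float,
) -> MixtureParams:
    """Re-seed collapsed components from the least-committed voxel."""
    d = Y.shape[1]
    pooled = np.cov(Y.T, ddof=1).reshape(d, d) + ridge * np.eye(d)
    order = np.argsort(R.max(axis=1))  # least confident first
    weights = params.weights.copy()
    means = params.means.copy()
    covs = params.covariances.copy()
    for rank, k in enumerate(np.flatnonzero(collapsed)):
        means[k] = Y[order[rank % len(order)]]
        covs[k] = pooled
        weights[k] = 1.0 / len(Y)
        logger.info("re-seeded collapsed component %d", k)
    weights /= weights.sum()
    return MixtureParams(weights=weights, means=means, covariances=covs)


def make_init(
    Y: np.ndarray, K: int, strategy: str = "kmeans", seed: int = 0
) -> InitSpec:
    """Deterministic mixture initialization from K-means centroids or random
    responsibilities."""
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    ridge = _ridge_for(Y)
    if strategy == "kmeans":
        # farthest-point-only seeding: empirically leads the spatially
        # constrained EM to better optima than D^2-sampled restarts
        km = kmeans_fit(Y, K, n_restarts=5, seed=seed, seeding="farthest")
        resid = Y - km.centroids[km.labels]
        pooled = np.diag(resid.var(axis=0) + ridge)
        return InitSpec(
            weights=np.full(K, 1.0 / K),
            means=km.centroids,
            covariances=np.repeat(pooled[None], K, axis=0),
            strategy=strategy,
            seed=seed,
        )
    if strategy == "random":
        rng = np.random.default_rng(seed)
        R = rng.dirichlet(np.ones(K), size=n)
        p = _m_step(Y, R, ridge)
        return InitSpec(
            weights=p.weights,
            means=p.means,
            covariances=p.covariances,
            strategy=strategy,
            seed=seed,
        )
    raise ValueError(f"unknown init strategy {strategy!r}")


# ---------------------------------------------------------------------------
# K-means


@dataclass
class KMeansResult:
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float


def _spread_out_seeds(
    Y: np.ndarray, K: int, first: int, rng: np.random.Generator | None
) -> np.ndarray:
    """Greedy spread-out seeding from point `first`.

    With ``rng`` None the next seed is always the point farthest from the
    chosen set; otherwise it is sampled proportionally to squared distance
    (D^2 sampling), which diversifies restarts.
    """
    idx = [first]
    mind = cdist(Y, Y[[first]], metric="sqeuclidean").ravel()
    for _ in range(1, K):
        if rng is None or mind.sum() <= 0:
            nxt = int(np.argmax(mind))
        else:
            nxt = int(rng.choice(len(Y), p=mind / mind.sum()))
        idx.append(nxt)
        mind = np.minimum(mind, cdist(Y, Y[[nxt]], metric="sqeuclidean").ravel())
    return Y[idx].copy()


def kmeans_fit(
    Y: np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    seeding: str = "hybrid",
) -> KMeansResult:
    """Lloyd's algorithm with greedy spread-out seeding, best of n_restarts.

    ``seeding="hybrid"`` (default) uses deterministic farthest-point seeding
    on the first restart and D^2 sampling afterwards, which explores enough to
    reach the global optimum on small instances; ``"farthest"`` uses
    farthest-point seeding on every restart (fully deterministic given the
    seeded choice of starting points).
    """
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    if n < K:
        raise ValueError(f"N={n} < K={K}")
    if seeding not in ("hybrid", "farthest"):
        raise ValueError(f"unknown seeding {seeding!r}")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for restart in range(n_restarts):
        use_rng = rng if (seeding == "hybrid" and restart > 0) else None
        cent = _spread_out_seeds(Y, K, first=int(rng.integers(n)), rng=use_rng)
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d2 = cdist(Y, cent, metric="sqeuclidean")
            new_labels = np.argmin(d2, axis=1)
            for k in range(K):
                members = new_labels == k
                if not members.any():  # empty cluster: re-seed from farthest point
                    far = int(np.argmax(d2[np.arange(n), new_labels]))
                    cent[k] = Y[far]
                    new_labels[far] = k
                    members = new_labels == k
                cent[k] = Y[members].mean(axis=0)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        d2 = cdist(Y, cent, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        if best is None or inertia < best.inertia:
            best = KMeansResult(centroids=cent.copy(), labels=labels, inertia=inertia)
    return best


# ---------------------------------------------------------------------------
# Fuzzy C-means


@dataclass
class FCMResult:
    centroids: np.ndarray
    U: np.ndarray
    objective: list
    n_iter: int = 0


def fcm_memberships(Y: np.ndarray, cent: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(Y, cent, metric="sqeuclidean")
    coincident = d2 <= 1e-300
    U = np.zeros_like(d2)
    any_co = coincident.any(axis=1)
    if any_co.any():
        # crisp membership for the nearest coincident centroid
        first = np.argmax(coincident[any_co], axis=1)
        U[np.flatnonzero(any_co), first] = 1.0
    rest = ~any_co
    if rest.any():
        inv = d2[rest] ** (-1.0 / (m - 1.0))
        U[rest] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_fit(
    Y: np.ndarray,
    K: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> FCMResult:
    """Standard fuzzy C-means alternating updates with fuzziness m > 1."""
    Y = np.asarray(Y, dtype=float)
    if m <= 1:
        raise ValueError("fuzziness m must exceed 1")
    n = len(Y)
    if n < K:
        raise ValueError(f"N={n} < K={K}")
    rng = np.random.default_rng(seed)
    cent = Y[rng.choice(n, size=K, replace=False)].astype(float)
    obj: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        U = fcm_memberships(Y, cent, m)
        Um = U**m
        cent = (Um.T @ Y) / np.maximum(Um.sum(axis=0)[:, None], 1e-300)
        d2 = cdist(Y, cent, metric="sqeuclidean")
        obj.append(float((Um * d2).sum()))
        if len(obj) > 1 and abs(obj[-2] - obj[-1]) <= tol * max(abs(obj[-2]), 1.0):
            break
    U = fcm_memberships(Y, cent, m)
    return FCMResult(centroids=cent, U=U, objective=obj, n_iter=it)


# ---------------------------------------------------------------------------
# Gaussian mixtures


def gmm_fit(
    Y: np.ndarray,
    K: int,
    init: InitSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[MixtureParams, ResponsibilityField]:
    """Classical EM for a full-covariance Gaussian mixture.

    The log-likelihood trace is recorded each iteration and is non-decreasing
    up to floating-point error.
    """
    return _em(Y, K, graph=None, init=init, tol=tol, max_iter=max_iter, seed=seed)


def constrained_gmm_fit(
    Y: np.ndarray,
    graph: NeighborGraph,
    K: int,
    init: InitSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[MixtureParams, ResponsibilityField]:
    """EM with spatial regularization through neighbor-averaged responsibilities.

    E-step: ``r_ik \\propto pi_k N(y_i | mu_k, Sigma_k) s_ik`` where ``s_ik``
    is the mean responsibility of voxel i's 26-connected masked neighbors from
    the previous iteration (uniform on the first iteration), each row
    renormalized.  M-step: standard weighted GMM updates.  The regularized
    objective ``sum_i log sum_k pi_k N(y_i) s_ik`` is traced; it is not
    guaranteed monotone and a non-monotone trace is logged, not an error.
    """
    if graph is None:
        raise ValueError("constrained fit requires a NeighborGraph (may be empty)")
    return _em(Y, K, graph=graph, init=init, tol=tol, max_iter=max_iter, seed=seed)


def _em(
    Y: np.ndarray,
    K: int,
    graph: NeighborGraph | None,
    init: InitSpec | None,
    tol: float,
    max_iter: int,
    seed: int,
) -> tuple[MixtureParams, ResponsibilityField]:
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    if n < K:
        raise ValueError(f"N={n} < K={K}")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite values in input")
    if init is None:
        init = make_init(Y, K, strategy="kmeans", seed=seed)
    ridge = _ridge_for(Y)
    params = MixtureParams(
        weights=init.weights.copy(),
        means=init.means.copy(),
        covariances=init.covariances.copy(),
    )

    log_s: np.ndarray | None = None  # None means uniform (first iteration)
    trace: list[float] = []
    R = np.full((n, K), 1.0 / K)
    converged = False
    reseed_counts = np.zeros(K, dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        base = np.log(params.weights)[None, :] + _log_gaussians(Y, params)
        logp = base if log_s is None else base + log_s
        lse = logsumexp(logp, axis=1)
        dead = ~np.isfinite(lse)
        if dead.any():
            # spatial prior zeroed every class for these voxels: fall back to
            # the likelihood-only posterior
            logp[dead] = base[dead]
            lse[dead] = logsumexp(logp[dead], axis=1)
        R = np.exp(logp - lse[:, None])
        obj = float(lse.sum())
        if trace and obj < trace[-1] - 1e-8 and graph is not None:
            logger.info("non-monotone objective at iteration %d", it)
        done = bool(trace) and abs(obj - trace[-1]) <= tol * max(abs(trace[-1]), 1.0)
        trace.append(obj)
        if done:
            converged = True
            break

        nk = R.sum(axis=0)
        collapsed = nk < 1.0
        if collapsed.any():
            reseed_counts[collapsed] += 1
            if reseed_counts.max() > 3:
                raise RuntimeError(
                    "mixture component collapsed more than 3 times; "
                    "reduce K or change initialization"
                )
            params = _reseed_collapsed(Y, R, params, collapsed, ridge)
            # a dead class has zero spatial support everywhere, so the prior
            # must be reset to uniform for one iteration or it dies again
            log_s = None
            continue
        params = _m_step(Y, R, ridge)
        if graph is not None and graph.adjacency.nnz > 0:
            S = neighbor_average(R, graph)
            with np.errstate(divide="ignore"):
                log_s = np.log(S)

    field_ = ResponsibilityField(
        R=R,
        coords=graph.coords if graph is not None else None,
        trace=trace,
        n_iter=it,
        converged=converged,
    )
    return params, field_
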