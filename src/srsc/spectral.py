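"""RBF affinity construction and normalized-Laplacian spectral embedding.

The affinity between two masked voxels i != j is
``W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` with ``W_ii = 0``.  The
embedding consists of the eigenvectors belonging to the k smallest
eigenvalues of the symmetric normalized Laplacian
``L = I - D^{-1/2} W D^{-1/2}`` (or, optionally, of the random-walk variant
obtained by rescaling those eigenvectors by ``D^{-1/2}``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from scipy.spatial.distance import pdist, squareform

from .io_model import FeatureMatrix

__all__ = [
    "AffinityMatrix",
    "SpectralEmbedding",
    "choose_sigma",
    "compute_affinity",
    "spectral_embed",
    "knn_sparsify",
]

# above this size a dense full eigendecomposition is not attempted
_DENSE_EIG_LIMIT = 10_000
# below this size use LAPACK directly instead of ARPACK
_DIRECT_EIG_LIMIT = 600


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative voxel-similarity matrix with zero diagonal."""

    W: np.ndarray
    sigma: float
    sigma_rule: str = "fixed"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def validate(self, atol: float = 0.0) -> None:
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("affinity matrix is not symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("affinity diagonal must be zero")
        if self.W.min() < -atol or self.W.max() > 1 + atol:
            raise ValueError("affinity entries must lie in [0, 1]")


@dataclass
class SpectralEmbedding:
    """k-dimensional Laplacian eigenvector embedding of the voxel graph."""

    Y: np.ndarray
    eigenvalues: np.ndarray
    row_normalized: bool
    zero_rows: np.ndarray | None = None
    isolated: np.ndarray | None = None


def choose_sigma(
    fm: FeatureMatrix | np.ndarray,
    rule: str = "median",
    seed: int = 0,
    max_exact: int = 2000,
) -> float:
    """Select the RBF scale sigma.

    ``rule`` is one of ``"median"`` (median of all pairwise Euclidean
    distances; exact for N <= ``max_exact``, otherwise computed over a seeded
    subsample of ``max_exact`` voxels), ``"median:<scale>"`` (the median
    multiplied by a positive factor — the plain median is typically too wide
    a kernel for fine cluster structure) or ``"fixed:<value>"``.
    """
    if rule.startswith("fixed:"):
        value = float(rule.split(":", 1)[1])
        if value <= 0:
            raise ValueError("fixed sigma must be positive")
        return value
    scale = 1.0
    if rule.startswith("median:"):
        scale = float(rule.split(":", 1)[1])
        if scale <= 0:
            raise ValueError("median scale must be positive")
    elif rule != "median":
        raise ValueError(f"unknown sigma rule {rule!r}")

    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 voxels to choose sigma")
    if n > max_exact:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, size=max_exact, replace=False)]
    d = pdist(X)
    med = float(np.median(d))
    if med <= 0:
        raise ValueError("degenerate features: all pairwise distances zero")
    return med * scale


def compute_affinity(
    fm: FeatureMatrix | np.ndarray, sigma: float, sigma_rule: str = "fixed"
) -> AffinityMatrix:
    """Build the dense RBF affinity matrix from voxel feature vectors."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 voxels")
    d2 = pdist(X, metric="sqeuclidean")
    if not np.isfinite(d2).all():
        raise ValueError("non-finite pairwise distances")
    W = squareform(np.exp(-d2 / (2.0 * sigma**2)))
    # squareform leaves an exactly-zero diagonal, matching the i == j branch
    return AffinityMatrix(W=W, sigma=float(sigma), sigma_rule=sigma_rule)


def knn_sparsify(aff: AffinityMatrix, m: int) -> AffinityMatrix:
    """Keep W_ij iff j is among the m strongest neighbors of i or vice versa."""
    n = aff.n
    if not 1 <= m < n:
        raise ValueError(f"m must satisfy 1 <= m < N, got {m} (N={n})")
    W = aff.W
    keep = np.zeros_like(W, dtype=bool)
    # indices of the m largest off-diagonal entries per row
    order = np.argsort(W, axis=1)[:, ::-1][:, :m]
    rows = np.repeat(np.arange(n), m)
    keep[rows, order.ravel()] = True
    keep |= keep.T  # symmetrized union
    out = np.where(keep, W, 0.0)
    np.fill_diagonal(out, 0.0)
    return AffinityMatrix(W=out, sigma=aff.sigma, sigma_rule=aff.sigma_rule)


def spectral_embed(
    aff: AffinityMatrix,
    k: int,
    row_normalize: bool = True,
    laplacian: str = "sym",
    max_isolated_frac: float = 0.05,
) -> SpectralEmbedding:
    """Embed voxels with the k lowest eigenvectors of the normalized Laplacian.

    Voxels with degree < 1e-12 are treated as isolated (their normalizer row
    and column are zeroed and they are reported); more than
    ``max_isolated_frac`` of them is an error suggesting a larger sigma.
    Eigenvector signs are fixed deterministically: the first component with
    magnitude > 1e-9 of each eigenvector is made positive.
    """
    if laplacian not in ("sym", "rw"):
        raise ValueError(f"unknown laplacian variant {laplacian!r}")
    W = aff.W
    n = W.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds N={n}")
    if n > _DENSE_EIG_LIMIT and np.count_nonzero(W) > n * 200:
        raise ValueError(
            f"dense eigendecomposition refused for N={n} > {_DENSE_EIG_LIMIT}; "
            "apply knn_sparsify first"
        )

    d = W.sum(axis=1)
    isolated = d < 1e-12
    if isolated.mean() > max_isolated_frac:
        raise ValueError(
            f"{int(isolated.sum())} of {n} voxels are isolated in the affinity "
            "graph; increase sigma"
        )
    d_inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, d)))

    # M = D^{-1/2} W D^{-1/2}; eigenvalues of L_sym are 1 - eig(M)
    M = (W * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]

    if n <= _DIRECT_EIG_LIMIT:
        L = np.eye(n) - M
        evals, evecs = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        mu, evecs = scipy.sparse.linalg.eigsh(M, k=k, which="LA", v0=v0)
        evals = 1.0 - mu
        order = np.argsort(evals)
        evals = evals[order]
        evecs = evecs[:, order]

    # deterministic sign: first component of magnitude > 1e-9 made positive
    for j in range(evecs.shape[1]):
        nz = np.flatnonzero(np.abs(evecs[:, j]) > 1e-9)
        if nz.size and evecs[nz[0], j] < 0:
            evecs[:, j] = -evecs[:, j]

    Y = evecs
    if laplacian == "rw":
        Y = Y * d_inv_sqrt[:, None]

    zero_rows = None
    if row_normalize:
        norms = np.linalg.norm(Y, axis=1)
        zero_rows = norms < 1e-12
        Y = Y / np.where(zero_rows, 1.0, norms)[:, None]

    return SpectralEmbedding(
        Y=Y,
        eigenvalues=np.asarray(evals, dtype=float),
        row_normalized=row_normalize,
        zero_rows=zero_rows,
        isolated=isolated if isolated.any() else None,
    )
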