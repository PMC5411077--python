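"""Starting basis matrices: deterministic NNDSVD and seeded uniform draws."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg

from .preprocessing import MultiOmicsCollection

__all__ = ["InitSpec", "random_init", "nndsvd_init"]

#: dense SVD is used when the concatenated matrix is at most this wide
_DENSE_SVD_LIMIT = 2000


@dataclass
class InitSpec:
    method: str = "nndsvd"  # {"nndsvd", "uniform"}
    seed: int | None = None
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("nndsvd", "uniform"):
            raise ValueError(f"unknown init method {self.method!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


def random_init(n: int, k: int, seed: int | None = None) -> np.ndarray:
    """An (n, k) matrix of i.i.d. U[0, 1] draws, reproducible given `seed`."""
    if k < 1 or n <= k:
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, k))


def _leading_svd(M: np.ndarray, k: int):
    n, p = M.shape
    if min(n, p) <= _DENSE_SVD_LIMIT or k >= min(n, p) - 1:
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        return U[:, :k], S[:k], Vt[:k]
    U, S, Vt = scipy.sparse.linalg.svds(M, k=k)
    order = np.argsort(S)[::-1]
    return U[:, order], S[order], Vt[order]


def nndsvd_init(
    collection: MultiOmicsCollection,
    k: int,
    theta: np.ndarray | None = None,
    epsilon: float = 1e-6,
) -> np.ndarray:
    """NNDSVD starting W from the weighted column-concatenation of all layers.

    The k leading singular triplets of ``[sqrt(theta_1) X^1 | ... |
    sqrt(theta_m) X^m]`` are converted to non-negative basis columns: the
    leading column is ``sqrt(sigma_1) u_1`` (sign-flipped positive); for
    j >= 2 the positive and negative parts of (u_j, v_j) are compared and
    the dominant same-signed pairing is kept, scaled by its combined norm.
    The construction contains no randomness.  Entries below `epsilon` are
    raised to `epsilon` so no column starts degenerate.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if theta is None:
        theta = collection.weights
    theta = np.asarray(theta, dtype=float)
    M = np.hstack(
        [np.sqrt(t) * lay.values for t, lay in zip(theta, collection.layers)]
    )
    if not np.any(M):
        raise ValueError("concatenated data matrix is all zero")
    n = M.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")

    U, S, Vt = _leading_svd(M, k)
    rank_tol = max(M.shape) * np.finfo(float).eps * S[0]
    if (S > rank_tol).sum() < k:
        raise ValueError(
            f"concatenated matrix has rank < {k}; choose a smaller k"
        )

    W = np.zeros((n, k))
    u0 = U[:, 0]
    if u0.sum() < 0:  # leading vector of a non-negative matrix is one-signed
        u0 = -u0
    W[:, 0] = np.sqrt(S[0]) * np.clip(u0, 0.0, None)

    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0.0, None), np.clip(-u, 0.0, None)
        vp, vn = np.clip(v, 0.0, None), np.clip(-v, 0.0, None)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        mp, mn = n_up * n_vp, n_un * n_vn
        if mp >= mn:
            if n_up > 0:
                W[:, j] = np.sqrt(S[j] * mp) * up / n_up
        else:
            if n_un > 0:
                W[:, j] = np.sqrt(S[j] * mn) * un / n_un

    return np.maximum(W, epsilon)
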