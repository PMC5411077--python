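"""The joint alternating-NNLS factorization loop.

All layers share one non-negative basis W (samples x k); each layer gets its
own coefficient matrix H^i (k x p_i).  Every update is an exactly solved
non-negativity-constrained least-squares problem, so the weighted objective

    Q = sum_i theta_i ||X^i - W H^i||_F^2

is non-increasing across outer iterations.  Cluster membership is the row
argmax of W after unit-norm column scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .initialization import nndsvd_init, random_init
from .nnls_core import nnls_multi
from .preprocessing import MultiOmicsCollection, OmicsLayer

logger = logging.getLogger(__name__)

__all__ = [
    "FactorizationState",
    "objective",
    "reconstruction_error",
    "update_H",
    "update_W",
    "assign_clusters",
    "connectivity_matrix",
    "mean_connectivity",
    "factorize",
    "run_multistart",
]


@dataclass
class FactorizationState:
    """Everything a finished (or halted) factorization run knows."""

    W: np.ndarray
    H: list[np.ndarray]
    k: int
    theta: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    reconstruction_error_trace: list[float] = field(default_factory=list)
    connectivity_history: list[np.ndarray] = field(default_factory=list)
    labels: np.ndarray | None = None
    converged: bool = False
    reason: str = "not run"
    n_iter: int = 0
    seed: int | None = None

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


def objective(
    collection: MultiOmicsCollection,
    W: np.ndarray,
    H: list[np.ndarray],
    theta: np.ndarray | None = None,
) -> float:
    """Weighted squared-Frobenius residual Q = sum_i theta_i ||X^i - W H^i||^2."""
    if theta is None:
        theta = collection.weights
    if len(H) != collection.m:
        raise ValueError(f"{len(H)} coefficient matrices for {collection.m} layers")
    q = 0.0
    for lay, Hi, t in zip(collection.layers, H, theta):
        if W.shape[0] != lay.n_samples or Hi.shape != (W.shape[1], lay.n_features):
            raise ValueError(
                f"dimension mismatch for layer {lay.name!r}: X is "
                f"{lay.values.shape}, W is {W.shape}, H is {Hi.shape}"
            )
        R = lay.values - W @ Hi
        q += float(t) * float(np.einsum("ij,ij->", R, R))
    return q


def reconstruction_error(
    collection: MultiOmicsCollection, W: np.ndarray, H: list[np.ndarray]
) -> float:
    """Sum over layers of entrywise absolute residuals sum|X^i - W H^i|."""
    return sum(
        float(np.abs(lay.values - W @ Hi).sum())
        for lay, Hi in zip(collection.layers, H)
    )


def update_H(layer: OmicsLayer, W: np.ndarray) -> np.ndarray:
    """Exact NNLS coefficient update: argmin_{H>=0} ||X - W H||^2, one
    independent NNLS per feature column with design W."""
    return nnls_multi(W, layer.values)


def update_W(
    collection: MultiOmicsCollection,
    H: list[np.ndarray],
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Exact NNLS basis update: argmin_{W>=0} sum_i theta_i ||X^i - W H^i||^2.

    Solved row-wise through the stacked design D = vstack(sqrt(theta_i) H_i^T)
    against targets vstack(sqrt(theta_i) (X^i)^T); all sample rows share D,
    so the whole update is one multi-RHS NNLS call.
    """
    if theta is None:
        theta = collection.weights
    root = np.sqrt(np.asarray(theta, dtype=float))
    D = np.vstack([r * Hi.T for r, Hi in zip(root, H)])
    C = np.vstack([r * lay.values.T for r, lay in zip(root, collection.layers)])
    return nnls_multi(D, C).T


def assign_clusters(W: np.ndarray) -> np.ndarray:
    """1-based row-argmax labels; ties go to the lowest column index and an
    all-zero row defaults to cluster 1 with a warning."""
    zero_rows = ~W.any(axis=1)
    if zero_rows.any():
        logger.warning(
            "%d sample(s) have an all-zero basis row; assigned to cluster 1",
            int(zero_rows.sum()),
        )
    return W.argmax(axis=1) + 1


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary n x n co-membership indicator (diagonal all 1)."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(np.uint8)


def mean_connectivity(history: list[np.ndarray], burn_in: int = 0) -> np.ndarray:
    """Entrywise mean of connectivity matrices, dropping up to `burn_in`
    leading iterations (always keeping at least one)."""
    if not history:
        raise ValueError("empty connectivity history")
    burn = min(burn_in, len(history) - 1)
    kept = history[burn:]
    return np.mean([c.astype(float) for c in kept], axis=0)


def _normalize_columns(W: np.ndarray, H: list[np.ndarray]) -> None:
    """Rescale W's columns to unit Euclidean norm in place, pushing the
    inverse scale into the rows of every H (objective-invariant)."""
    norms = np.linalg.norm(W, axis=0)
    ok = norms > 0
    W[:, ok] /= norms[ok]
    for Hi in H:
        Hi[ok, :] *= norms[ok, None]


def factorize(
    collection: MultiOmicsCollection,
    k: int,
    W_init: np.ndarray,
    theta: np.ndarray | None = None,
    tol: float = 1e-4,
    stability_count: int = 50,
    max_iter: int = 200,
    seed: int | None = None,
) -> FactorizationState:
    """Alternate exact NNLS updates of {H^i} then W until convergence.

    Stops when the connectivity matrix is unchanged for `stability_count`
    consecutive iterations, or the relative change of the absolute
    reconstruction error drops below `tol`, or `max_iter` is reached (the
    last is flagged as non-convergence, not raised).
    """
    n = collection.n
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    W = np.asarray(W_init, dtype=float)
    if W.shape != (n, k):
        raise ValueError(f"W_init must be {(n, k)}, got {W.shape}")
    if (W < 0).any():
        raise ValueError("W_init must be non-negative")
    if theta is None:
        theta = collection.weights
    theta = np.asarray(theta, dtype=float)

    state = FactorizationState(W=W.copy(), H=[], k=k, theta=theta, seed=seed)
    W = state.W
    prev_connectivity: np.ndarray | None = None
    prev_error: float | None = None
    stable = 0

    for it in range(1, max_iter + 1):
        H = [update_H(lay, W) for lay in collection.layers]
        W = update_W(collection, H, theta)
        _normalize_columns(W, H)
        state.W, state.H = W, H

        labels = assign_clusters(W)
        conn = connectivity_matrix(labels)
        err = reconstruction_error(collection, W, H)
        state.objective_trace.append(objective(collection, W, H, theta))
        state.reconstruction_error_trace.append(err)
        state.connectivity_history.append(conn)
        state.labels = labels
        state.n_iter = it

        if prev_connectivity is not None and np.array_equal(conn, prev_connectivity):
            stable += 1
        else:
            stable = 0
        prev_connectivity = conn

        if stable >= stability_count:
            state.converged = True
            state.reason = f"connectivity stable for {stability_count} iterations"
            break
        if prev_error is not None and prev_error > 0:
            if abs(err - prev_error) / prev_error < tol:
                state.converged = True
                state.reason = f"reconstruction-error change below {tol}"
                break
        prev_error = err
    else:
        state.converged = False
        state.reason = f"max_iter ({max_iter}) reached"

    return state


def run_multistart(
    collection: MultiOmicsCollection,
    k: int,
    n_init: int = 30,
    base_seed: int = 0,
    init: str = "mixed",
    theta: np.ndarray | None = None,
    tol: float = 1e-4,
    stability_count: int = 50,
    max_iter: int = 200,
    consensus_burn_in: int = 10,
) -> tuple[FactorizationState, list[dict]]:
    """Run `n_init` factorizations and keep the one with the smallest Q.

    With init='mixed' (the default) the first start is the deterministic
    NNDSVD matrix and the remaining n_init - 1 are U[0,1] draws seeded
    ``base_seed + run``; 'uniform' and 'nndsvd' force a single scheme.
    Returns the best state plus one summary dict per run (final Q, labels,
    iteration-averaged consensus, convergence metadata).
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if init not in ("mixed", "uniform", "nndsvd"):
        raise ValueError(f"unknown init scheme {init!r}")
    if theta is None:
        theta = collection.weights

    best: FactorizationState | None = None
    summaries: list[dict] = []
    for run in range(n_init):
        use_nndsvd = (init == "nndsvd") or (init == "mixed" and run == 0)
        seed = base_seed + run
        if use_nndsvd:
            W0 = nndsvd_init(collection, k, theta=theta)
        else:
            W0 = random_init(collection.n, k, seed=seed)
        state = factorize(
            collection, k, W0, theta=theta, tol=tol,
            stability_count=stability_count, max_iter=max_iter, seed=seed,
        )
        final_rss = sum(
            float(np.einsum("ij,ij->", R, R))
            for R in (lay.values - state.W @ Hi
                      for lay, Hi in zip(collection.layers, state.H))
        )
        summaries.append(
            {
                "run": run,
                "init": "nndsvd" if use_nndsvd else "uniform",
                "seed": seed,
                "final_objective": state.final_objective,
                "final_rss": final_rss,
                "labels": state.labels,
                "consensus": mean_connectivity(
                    state.connectivity_history, burn_in=consensus_burn_in
                ),
                "n_iter": state.n_iter,
                "converged": state.converged,
                "reason": state.reason,
            }
        )
        if best is None or state.final_objective < best.final_objective:
            best = state
    assert best is not None
    return best, summaries
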