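"""Non-negativity-constrained least squares with many right-hand sides.

This is the numerical kernel of both alternating-least-squares updates:
``min ||B - A X||_F^2  subject to  X >= 0`` solved exactly, column by
column, using the fast combinatorial active-set strategy of Van Benthem &
Keenan (columns sharing a passive set are solved together through one
factorization of the normal equations).  The solver is observationally
identical to running a Lawson-Hanson active-set solve on every column
independently; grouping is purely a speed optimisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

logger = logging.getLogger(__name__)

__all__ = ["NNLSProblem", "nnls_solve", "nnls_multi", "kkt_violation"]


@dataclass
class NNLSProblem:
    """A multi right-hand-side NNLS instance ``min ||targets - design @ X||``."""

    design: np.ndarray  # (q, r)
    targets: np.ndarray  # (q, s); each column is one right-hand side


def nnls_solve(problem: NNLSProblem, tol: float | None = None) -> np.ndarray:
    """Solve an :class:`NNLSProblem`, returning the (r, s) solution matrix."""
    return nnls_multi(problem.design, problem.targets, tol=tol)


def _solve_normal(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve the SPD system M X = Y, falling back to least-norm lstsq when
    the active-set submatrix is rank deficient."""
    try:
        c, low = scipy.linalg.cho_factor(M)
        return scipy.linalg.cho_solve((c, low), Y)
    except (scipy.linalg.LinAlgError, ValueError):
        return np.linalg.lstsq(M, Y, rcond=None)[0]


def _cssls(AtA: np.ndarray, AtB: np.ndarray, P: np.ndarray | None = None) -> np.ndarray:
    """Combinatorial subspace least squares: solve the normal equations
    restricted to each column's passive set, grouping columns with
    identical passive sets so each unique set is factorized once."""
    X = np.zeros_like(AtB)
    if P is None:
        X[:] = _solve_normal(AtA, AtB)
        return X
    uniq, inverse = np.unique(P, axis=1, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    for g in range(uniq.shape[1]):
        passive = uniq[:, g]
        if not passive.any():
            continue
        cols = np.flatnonzero(inverse == g)
        sub = _solve_normal(AtA[np.ix_(passive, passive)], AtB[np.ix_(passive, cols)])
        X[np.ix_(passive, cols)] = sub
    return X


def nnls_multi(
    A: np.ndarray,
    B: np.ndarray,
    tol: float | None = None,
    max_outer: int | None = None,
) -> np.ndarray:
    """Solve ``min_X ||B - A X||_F^2 s.t. X >= 0`` for all columns of B.

    Parameters
    ----------
    A : (q, r) design matrix.
    B : (q, s) matrix of right-hand sides (a 1-D vector is treated as one
        column and returned as a (r,) vector).
    tol : KKT tolerance; defaults to ``1e-10 * max(1, ||A.T B||_inf)`` so the
        stopping rule is dimensionless.
    max_outer : safety cap on active-set growth passes (default ``3r + 30``).

    Returns
    -------
    X : (r, s) non-negative solution; each column satisfies the NNLS KKT
        conditions to within ``tol``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    single_rhs = B.ndim == 1
    if single_rhs:
        B = B[:, None]
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("design and targets must be 2-D")
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"design has {A.shape[0]} rows but targets have {B.shape[0]}"
        )
    if not np.isfinite(A).all():
        raise ValueError("non-finite entries in design matrix")
    if not np.isfinite(B).all():
        raise ValueError("non-finite entries in target matrix")

    q, r = A.shape
    s = B.shape[1]

    # All-zero design columns admit no signal: their solution rows are 0.
    col_ss = np.einsum("ij,ij->j", A, A)
    dead = col_ss == 0.0
    if dead.any():
        logger.warning(
            "design has %d all-zero column(s); corresponding solution rows set to 0",
            int(dead.sum()),
        )
        live = ~dead
        X = np.zeros((r, s))
        if live.any():
            X[live] = nnls_multi(A[:, live], B, tol=tol, max_outer=max_outer)
        return X[:, 0] if single_rhs else X

    AtA = A.T @ A
    AtB = A.T @ B
    if tol is None:
        tol = 1e-10 * max(1.0, float(np.abs(AtB).max()))
    if max_outer is None:
        max_outer = 3 * r + 30

    # Unconstrained start: columns whose solution is already feasible are done.
    X = _cssls(AtA, AtB)
    P = X > 0.0
    X[~P] = 0.0
    Xf = X.copy()  # last feasible iterate, per column
    F = np.flatnonzero(~P.all(axis=0))

    outer = 0
    while F.size:
        outer += 1
        if outer > max_outer:
            # Extremely rare cycling guard: finish stragglers one at a time
            # with the reference single-RHS solver.
            logger.warning(
                "fast combinatorial NNLS hit iteration cap; falling back to "
                "per-column solver for %d column(s)", F.size,
            )
            for j in F:
                X[:, j], _ = scipy.optimize.nnls(A, B[:, j])
            break
        X[:, F] = _cssls(AtA, AtB[:, F], P[:, F])

        # Inner loop: march infeasible columns back to the boundary
        # (Lawson-Hanson step toward the last feasible point).
        inner = 0
        while True:
            inner += 1
            neg = (X[:, F] < 0.0) & P[:, F]
            bad = np.flatnonzero(neg.any(axis=0))
            if bad.size == 0 or inner > max_outer:
                break
            cols = F[bad]
            for j in cols:
                mask = P[:, j] & (X[:, j] < 0.0)
                denom = Xf[mask, j] - X[mask, j]
                alpha = float(np.min(Xf[mask, j] / denom))
                X[:, j] = Xf[:, j] + alpha * (X[:, j] - Xf[:, j])
                # Zero out the variable(s) that reached the boundary.
                hit = P[:, j] & (X[:, j] <= max(tol, 1e-14))
                P[hit, j] = False
                X[hit, j] = 0.0
            X[:, cols] = _cssls(AtA, AtB[:, cols], P[:, cols])

        np.maximum(X[:, F], 0.0, out=X[:, F])
        Xf[:, F] = X[:, F]

        # Optimality: the projected gradient on the active (zero) set must
        # be non-positive; otherwise free the worst violator.
        G = AtB[:, F] - AtA @ X[:, F]
        G[P[:, F]] = -np.inf
        worst = np.argmax(G, axis=0)
        violating = G[worst, np.arange(F.size)] > tol
        if not violating.any():
            break
        grow = np.flatnonzero(violating)
        P[worst[grow], F[grow]] = True
        F = F[grow]

    if single_rhs:
        return X[:, 0]
    return X


def kkt_violation(A: np.ndarray, B: np.ndarray, X: np.ndarray) -> float:
    """Maximum KKT violation of a candidate NNLS solution (0 when optimal).

    Checks complementary slackness of ``min ||B - A X||, X >= 0``:
    the gradient ``A.T (A X - B)`` must be >= 0 where X is 0 and ~0 where
    X > 0; negativity of X itself also counts as violation.
    """
    B = np.atleast_2d(B.T).T
    X = np.atleast_2d(X.T).T
    G = A.T @ (A @ X - B)
    active = X <= 0
    v = 0.0
    if active.any():
        v = max(v, float(np.maximum(-G[active], 0.0).max(initial=0.0)))
    if (~active).any():
        v = max(v, float(np.abs(G[~active]).max(initial=0.0)))
    v = max(v, float(np.maximum(-X, 0.0).max(initial=0.0)))
    return v
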