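"""Choosing the number of clusters k.

Five measures are computed over a candidate grid: average silhouette width
on the consensus-derived distance 1 - Cbar, cophenetic correlation of that
distance, the dispersion of the consensus matrix, the residual sum of
squares, and a cross-validated Cluster Prediction Index (mean adjusted Rand
index between test labels predicted from training coefficients and labels
from clustering the test set independently).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .evaluation_metrics import adjusted_rand_index
from .factorization import (
    FactorizationState,
    assign_clusters,
    mean_connectivity,
    run_multistart,
)
from .nnls_core import nnls_multi
from .preprocessing import MultiOmicsCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusMatrix",
    "KSelectionProfile",
    "CPIConfig",
    "consensus_matrix",
    "silhouette_on_consensus",
    "cophenetic_coefficient",
    "dispersion_coefficient",
    "rss",
    "predict_basis",
    "cluster_prediction_index",
    "scan_k",
    "select_k",
]

MEASURES = ("silhouette", "cophenetic", "dispersion", "rss", "cpi")


@dataclass
class ConsensusMatrix:
    """Average of binary connectivity matrices; entries are co-clustering
    probabilities."""

    values: np.ndarray
    count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def distance(self) -> np.ndarray:
        """1 - Cbar with an exactly-zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class KSelectionProfile:
    """Per-k, per-run (or per-repetition) values of the selection measures."""

    k_values: list[int]
    values: dict[str, np.ndarray] = field(default_factory=dict)  # (runs, k)

    def mean(self, measure: str) -> np.ndarray:
        if measure not in self.values:
            raise KeyError(f"measure {measure!r} not in profile")
        return np.nanmean(self.values[measure], axis=0)


@dataclass
class CPIConfig:
    k_range: list[int]
    n_repeats: int = 20
    train_fraction: float = 2 / 3
    n_init_train: int = 10
    n_init_test: int = 10
    base_seed: int = 0
    tol: float = 1e-4
    stability_count: int = 50
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def consensus_matrix(
    connectivity_history: list[np.ndarray], burn_in: int = 0
) -> ConsensusMatrix:
    """Entrywise mean of a run's connectivity matrices (optionally dropping
    a burn-in prefix)."""
    values = mean_connectivity(connectivity_history, burn_in=burn_in)
    return ConsensusMatrix(values=values, count=len(connectivity_history) - min(burn_in, len(connectivity_history) - 1))


def silhouette_on_consensus(cbar: ConsensusMatrix, labels: np.ndarray) -> float:
    """Average silhouette width with d = 1 - Cbar as the distance matrix.

    For each sample: a = mean distance to its own cluster (excluding
    itself), b = smallest mean distance to another cluster, s = (b - a) /
    max(a, b).  Samples in singleton clusters score 0.
    """
    d = cbar.distance()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two non-empty clusters")
    n = cbar.n
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for j in range(n):
        own = members[labels[j]]
        if len(own) == 1:
            continue
        a = d[j, own].sum() / (len(own) - 1)
        b = min(d[j, members[c]].mean() for c in uniq if c != labels[j])
        denom = max(a, b)
        if denom > 0:
            s[j] = (b - a) / denom
    return float(s.mean())


def cophenetic_coefficient(cbar: ConsensusMatrix, linkage: str = "average") -> float:
    """Pearson correlation between 1 - Cbar and the cophenetic distances of
    its hierarchical clustering (average linkage by default)."""
    if cbar.n < 3:
        raise ValueError("cophenetic correlation needs n >= 3")
    dm = squareform(cbar.distance(), checks=False)
    if np.ptp(dm) == 0:
        raise ValueError("constant distance matrix; cophenetic correlation undefined")
    Z = sch.linkage(dm, method=linkage)
    c, _ = sch.cophenet(Z, dm)
    return float(c)


def dispersion_coefficient(cbar: ConsensusMatrix) -> float:
    """rho = (1/n^2) sum_ij 4 (Cbar_ij - 1/2)^2; 1 iff Cbar is binary."""
    return float(np.mean(4.0 * (cbar.values - 0.5) ** 2))


def rss(collection: MultiOmicsCollection, W: np.ndarray, H: list[np.ndarray]) -> float:
    """Unweighted residual sum of squares sum_i ||X^i - W H^i||_F^2."""
    total = 0.0
    for lay, Hi in zip(collection.layers, H):
        R = lay.values - W @ Hi
        total += float(np.einsum("ij,ij->", R, R))
    return total


def predict_basis(
    collection: MultiOmicsCollection,
    H_train: list[np.ndarray],
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Project new samples onto trained coefficients: argmin_{W>=0}
    sum_i theta_i ||X^i - W H^i_train||^2 via one stacked NNLS."""
    if theta is None:
        theta = collection.weights
    root = np.sqrt(np.asarray(theta, dtype=float))
    D = np.vstack([r * Hi.T for r, Hi in zip(root, H_train)])
    C = np.vstack([r * lay.values.T for r, lay in zip(root, collection.layers)])
    return nnls_multi(D, C).T


def cluster_prediction_index(
    collection: MultiOmicsCollection, config: CPIConfig
) -> KSelectionProfile:
    """Cross-validated CPI over config.k_range.

    Each repetition splits the samples into train/test, fits the joint
    factorization on the training samples, predicts test labels through the
    trained coefficient matrices, clusters the test samples independently,
    and scores the agreement with the adjusted Rand index.  CPI(k) is the
    mean over repetitions.
    """
    n = collection.n
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    ks = list(config.k_range)
    values = np.full((config.n_repeats, len(ks)), np.nan)

    for rep in range(config.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, rep]))
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
        train = collection.subset_samples(train_idx)
        test = collection.subset_samples(test_idx)
        for kk, k in enumerate(ks):
            if k >= len(test_idx) or k >= len(train_idx):
                logger.warning("skipping k=%d: partition smaller than k", k)
                continue
            sub_seed = int(
                np.random.SeedSequence([config.base_seed, rep, k]).generate_state(1)[0]
                % (2**31)
            )
            best_train, _ = run_multistart(
                train, k, n_init=config.n_init_train, base_seed=sub_seed,
                tol=config.tol, stability_count=config.stability_count,
                max_iter=config.max_iter,
            )
            W_test = predict_basis(test, best_train.H, theta=collection.weights)
            predicted = assign_clusters(W_test)
            best_test, _ = run_multistart(
                test, k, n_init=config.n_init_test, base_seed=sub_seed + 1,
                tol=config.tol, stability_count=config.stability_count,
                max_iter=config.max_iter,
            )
            observed = best_test.labels
            if len(np.unique(observed)) == 1:
                logger.warning("single-cluster observed partition at k=%d", k)
            values[rep, kk] = adjusted_rand_index(predicted, observed)

    return KSelectionProfile(k_values=ks, values={"cpi": values})


def scan_k(
    collection: MultiOmicsCollection,
    k_range,
    n_init: int = 30,
    base_seed: int = 0,
    consensus_burn_in: int = 10,
    consensus_mode: str = "iterations",
    tol: float = 1e-4,
    stability_count: int = 50,
    max_iter: int = 200,
) -> tuple[KSelectionProfile, dict[int, FactorizationState]]:
    """Per-run silhouette / cophenetic / dispersion / RSS over a k grid.

    consensus_mode='iterations' (default) builds each run's consensus from
    its own post-burn-in connectivity history; 'runs' uses one across-runs
    consensus per k (every run of that k then shares the same consensus
    value, Brunet-style).
    """
    if consensus_mode not in ("iterations", "runs"):
        raise ValueError(f"unknown consensus_mode {consensus_mode!r}")
    ks = list(k_range)
    out = {
        m: np.full((n_init, len(ks)), np.nan)
        for m in ("silhouette", "cophenetic", "dispersion", "rss")
    }
    best_states: dict[int, FactorizationState] = {}
    for kk, k in enumerate(ks):
        best, summaries = run_multistart(
            collection, k, n_init=n_init, base_seed=base_seed + 1000 * k,
            tol=tol, stability_count=stability_count, max_iter=max_iter,
            consensus_burn_in=consensus_burn_in,
        )
        best_states[k] = best
        if consensus_mode == "runs":
            # Brunet-style: average the final connectivity matrix of every run.
            from .factorization import connectivity_matrix as _conn

            shared = ConsensusMatrix(
                values=np.mean(
                    [_conn(s["labels"]).astype(float) for s in summaries], axis=0
                ),
                count=len(summaries),
            )
        for r, summ in enumerate(summaries):
            if consensus_mode == "iterations":
                cbar = ConsensusMatrix(values=summ["consensus"], count=summ["n_iter"])
            else:
                cbar = shared
            labels = summ["labels"]
            try:
                out["silhouette"][r, kk] = silhouette_on_consensus(cbar, labels)
            except ValueError:
                out["silhouette"][r, kk] = np.nan
            try:
                out["cophenetic"][r, kk] = cophenetic_coefficient(cbar)
            except ValueError:
                out["cophenetic"][r, kk] = np.nan
            out["dispersion"][r, kk] = dispersion_coefficient(cbar)
            out["rss"][r, kk] = summ["final_rss"]
    profile = KSelectionProfile(k_values=ks, values=out)
    return profile, best_states


def select_k(profile: KSelectionProfile, measure: str) -> int:
    """Pick k: argmax of the mean for silhouette/cophenetic/dispersion/cpi
    (ties to the smallest k); for RSS, the elbow as the largest discrete
    second difference of the mean curve."""
    if measure not in profile.values:
        raise ValueError(f"measure {measure!r} missing from profile")
    ks = np.asarray(profile.k_values)
    means = profile.mean(measure)
    if measure == "rss":
        if len(ks) < 3:
            raise ValueError("RSS elbow rule needs at least 3 candidate k")
        second = means[:-2] - 2 * means[1:-1] + means[2:]
        return int(ks[1:-1][int(np.argmax(second))])
    return int(ks[int(np.argmax(means))])
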