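"""Multi-layer synthetic datasets with known cluster structure.

Several layers share one sample-to-cluster assignment.  Within each layer a
chosen proportion of features is "differential": every cluster adds a mean
shift of magnitude ``effect_size * noise_sd`` with a cluster-specific sign
pattern (patterns are mutually distinct, so every pair of clusters is
separated on the differential set).  An optional per-sample latent factor
shared by all layers mimics inter-layer correlation.  Layers are then
shifted non-negative and rescaled to unit max, ready for factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .preprocessing import (
    MultiOmicsCollection,
    OmicsLayer,
    rescale_unit_max,
    shift_nonnegative,
)

__all__ = ["LayerSpec", "SimulationSpec", "SimulatedCollection", "simulate", "paper_grid"]


@dataclass
class LayerSpec:
    p: int
    noise_sd: float = 1.0
    diff_prop: float = 0.25

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("layer must have at least one feature")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.diff_prop <= 1.0):
            raise ValueError("diff_prop must be in [0, 1]")


@dataclass
class SimulationSpec:
    k_true: int
    n: int
    layers: list[LayerSpec]
    effect_size: float = 2.0
    cluster_proportions: list[float] | None = None
    cross_layer_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n < 5 * self.k_true:
            raise ValueError(f"need n >= 5 * k_true, got n={self.n}, k_true={self.k_true}")
        if not self.layers:
            raise ValueError("at least one layer spec required")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.cross_layer_coupling <= 1.0):
            raise ValueError("cross_layer_coupling must be in [0, 1]")
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.k_true] * self.k_true
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.k_true:
            raise ValueError("cluster_proportions must have length k_true")
        if (props <= 0).any() or not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster_proportions must be positive and sum to 1")


@dataclass
class SimulatedCollection:
    collection: MultiOmicsCollection
    truth: np.ndarray
    differential_features: list[np.ndarray] = field(default_factory=list)
    spec: SimulationSpec | None = None


def _cluster_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment: deterministic, each cluster >= 1."""
    raw = n * proportions
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    remainder = raw - np.floor(raw)
    while counts.sum() < n:
        order = np.argsort(-remainder)
        for c in order:
            if counts.sum() == n:
                break
            counts[c] += 1
    return counts


def _sign_patterns(rng: np.random.Generator, k: int, d: int) -> np.ndarray:
    """(k, d) matrix of +-1 rows built from distinct Hadamard rows.

    Distinct rows of a Hadamard matrix are orthogonal, so after tiling to
    width d every pair of clusters sits at (nearly) the same distance on the
    differential set - no cluster pair is privileged, which is what keeps
    under-clustered merges ambiguous.  The row-to-cluster mapping, a random
    column permutation and per-feature sign flips (all distance-preserving)
    are drawn from `rng`.
    """
    if k > 2**d:
        raise ValueError(f"cannot build {k} distinct sign patterns over {d} features")
    order = 1
    while order < k:
        order *= 2
    Hd = scipy.linalg.hadamard(order).astype(float)
    rows = rng.choice(order, size=k, replace=False)
    reps = -(-d // order)  # ceil
    S = np.tile(Hd[rows], (1, reps))[:, :d]
    S = S[:, rng.permutation(d)]
    S *= rng.choice([-1.0, 1.0], size=d)
    return S


def simulate(spec: SimulationSpec) -> SimulatedCollection:
    """Draw one multi-layer dataset from `spec`; reproducible given its seed."""
    rng = np.random.default_rng(spec.seed)
    props = np.asarray(spec.cluster_proportions, dtype=float)
    counts = _cluster_counts(spec.n, props)
    truth = np.repeat(np.arange(1, spec.k_true + 1), counts)
    rng.shuffle(truth)

    latent = rng.standard_normal(spec.n)

    layers: list[OmicsLayer] = []
    diff_sets: list[np.ndarray] = []
    for li, lspec in enumerate(spec.layers):
        p = lspec.p
        d = int(round(lspec.diff_prop * p))
        diff_idx = np.sort(rng.choice(p, size=d, replace=False))
        baseline = rng.normal(0.0, 1.0, size=p)
        X = baseline[None, :] + rng.normal(0.0, lspec.noise_sd, size=(spec.n, p))
        if d > 0 and spec.effect_size > 0 and spec.k_true > 1:
            S = _sign_patterns(rng, spec.k_true, d)
            X[:, diff_idx] += spec.effect_size * lspec.noise_sd * S[truth - 1]
        if spec.cross_layer_coupling > 0:
            X += spec.cross_layer_coupling * lspec.noise_sd * latent[:, None]
        X = rescale_unit_max(shift_nonnegative(X))
        layers.append(
            OmicsLayer(
                values=X,
                sample_ids=[f"S{j + 1}" for j in range(spec.n)],
                feature_ids=[f"L{li + 1}F{j + 1}" for j in range(p)],
                weight=1.0,
                name=f"layer{li + 1}",
            )
        )
        diff_sets.append(diff_idx)

    return SimulatedCollection(
        collection=MultiOmicsCollection(layers),
        truth=truth,
        differential_features=diff_sets,
        spec=spec,
    )


def paper_grid(
    n: int = 90,
    layer_sizes: tuple[int, ...] = (60, 60, 60),
    noise_sd: float = 1.0,
    diff_prop: float = 0.25,
    base_seed: int = 0,
) -> list[SimulationSpec]:
    """The factorial simulation design: true cluster counts 2..6 crossed
    with effect sizes 0.0 to 4.0 in steps of 0.5 (45 specs), a quarter of
    the features differential in every layer."""
    specs = []
    effect_sizes = [0.5 * s for s in range(9)]
    for k_true in range(2, 7):
        for effect in effect_sizes:
            specs.append(
                SimulationSpec(
                    k_true=k_true,
                    n=n,
                    layers=[
                        LayerSpec(p=p, noise_sd=noise_sd, diff_prop=diff_prop)
                        for p in layer_sizes
                    ],
                    effect_size=effect,
                    seed=base_seed + 100 * k_true + int(effect * 2),
                )
            )
    return specs
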