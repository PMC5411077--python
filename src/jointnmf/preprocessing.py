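"""Layer containers and the transforms that make raw omics matrices
factorizable: non-negative shift, unit-max rescale, feature filtering, and
data-driven layer weights.

Matrices are oriented samples-in-rows (n x p).  All layers of a collection
must share the same ordered sample IDs; alignment is by ID intersection and
never silently reorders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OmicsLayer",
    "MultiOmicsCollection",
    "shift_nonnegative",
    "rescale_unit_max",
    "compute_weights",
    "filter_features",
    "prepare_layer",
    "prepare_collection",
    "align_layers",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class OmicsLayer:
    """One samples-by-features matrix with identifiers and a weight."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    weight: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample IDs for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature IDs for {p} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not self.weight > 0:
            raise ValueError(f"layer weight must be > 0, got {self.weight}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiOmicsCollection:
    """An ordered list of layers aligned on one ordered sample set."""

    layers: list[OmicsLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("collection needs at least one layer")
        ref = self.layers[0].sample_ids
        for lay in self.layers[1:]:
            if lay.sample_ids != ref:
                raise ValueError(
                    "layers do not share identical ordered sample IDs "
                    f"(layer {lay.name or self.layers.index(lay)})"
                )

    @property
    def n(self) -> int:
        return self.layers[0].n_samples

    @property
    def m(self) -> int:
        return len(self.layers)

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def weights(self) -> np.ndarray:
        return np.array([lay.weight for lay in self.layers], dtype=float)

    def subset_samples(self, index: np.ndarray) -> "MultiOmicsCollection":
        """New collection restricted to samples at integer positions `index`."""
        index = np.asarray(index)
        layers = [
            replace(
                lay,
                values=lay.values[index],
                sample_ids=[lay.sample_ids[i] for i in index],
            )
            for lay in self.layers
        ]
        return MultiOmicsCollection(layers)


def shift_nonnegative(X: np.ndarray) -> np.ndarray:
    """Add |min(X)| to every entry when the minimum is negative.

    A matrix that is already non-negative is returned unchanged (same
    values, new array).  Non-finite entries are rejected with the offending
    cell named.
    """
    X = np.asarray(X, dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite entry at row {i}, column {j}: {X[i, j]}")
    lo = float(X.min())
    if lo < 0:
        return X - lo
    return X.copy()


def rescale_unit_max(X: np.ndarray) -> np.ndarray:
    """Divide a non-negative matrix by its maximum, mapping entries to [0, 1]."""
    X = np.asarray(X, dtype=float)
    hi = float(X.max())
    if hi <= 0:
        raise ValueError("cannot rescale an all-zero matrix (max is 0)")
    return X / hi


def prepare_layer(layer: OmicsLayer) -> OmicsLayer:
    """Shift to non-negative then rescale to unit max."""
    return replace(layer, values=rescale_unit_max(shift_nonnegative(layer.values)))


def prepare_collection(
    collection: MultiOmicsCollection, weights: str | Sequence[float] = "equal"
) -> MultiOmicsCollection:
    """Prepare every layer and set weights ('equal', 'auto', or explicit)."""
    prepared = MultiOmicsCollection([prepare_layer(lay) for lay in collection.layers])
    if weights == "auto":
        theta = compute_weights(prepared)
    elif weights == "equal":
        theta = [1.0] * prepared.m
    else:
        theta = [float(w) for w in weights]
        if len(theta) != prepared.m:
            raise ValueError(f"{len(theta)} weights for {prepared.m} layers")
    return MultiOmicsCollection(
        [replace(lay, weight=t) for lay, t in zip(prepared.layers, theta)]
    )


def compute_weights(collection: MultiOmicsCollection) -> list[float]:
    """Data-driven layer weights: max mean-sum-of-squares over this layer's.

    meanSS_i is the mean of the squared entries of layer i (over all n*p_i
    cells), and theta_i = max_j(meanSS_j) / meanSS_i, so the largest-scale
    layer gets weight 1 and every weight is >= 1.
    """
    mss = []
    for lay in collection.layers:
        if lay.values.size == 0:
            raise ValueError(f"layer {lay.name!r} is empty")
        v = float(np.mean(lay.values**2))
        if v == 0.0:
            raise ValueError(
                f"layer {lay.name!r} has zero mean sum of squares; cannot weight"
            )
        mss.append(v)
    top = max(mss)
    return [top / v for v in mss]


def filter_features(
    layer: OmicsLayer,
    sd_min: float | None = None,
    max_zero_prop: float | None = None,
) -> OmicsLayer:
    """Keep features with sample SD >= sd_min and/or zero-proportion strictly
    below max_zero_prop; feature order is preserved."""
    keep = np.ones(layer.n_features, dtype=bool)
    if sd_min is not None:
        if not np.isfinite(sd_min):
            raise ValueError("sd_min must be finite")
        sd = np.std(layer.values, axis=0, ddof=1)
        keep &= sd >= sd_min
    if max_zero_prop is not None:
        if not (0.0 <= max_zero_prop <= 1.0):
            raise ValueError("max_zero_prop must be in [0, 1]")
        zero_prop = np.mean(layer.values == 0.0, axis=0)
        keep &= zero_prop < max_zero_prop
    if not keep.any():
        raise ValueError(
            f"feature filter removed all {layer.n_features} features of layer "
            f"{layer.name!r}"
        )
    idx = np.flatnonzero(keep)
    return replace(
        layer,
        values=layer.values[:, idx],
        feature_ids=[layer.feature_ids[i] for i in idx],
    )


def align_layers(layers: Sequence[OmicsLayer]) -> MultiOmicsCollection:
    """Restrict each layer to the samples common to all, erroring if the
    surviving orders disagree (no silent reordering)."""
    common = set(layers[0].sample_ids)
    for lay in layers[1:]:
        common &= set(lay.sample_ids)
    if not common:
        raise ValueError("layers share no sample IDs")
    aligned = []
    for lay in layers:
        pos = [i for i, s in enumerate(lay.sample_ids) if s in common]
        aligned.append(
            replace(
                lay,
                values=lay.values[pos],
                sample_ids=[lay.sample_ids[i] for i in pos],
            )
        )
    ref = aligned[0].sample_ids
    for lay in aligned[1:]:
        if lay.sample_ids != ref:
            raise ValueError(
                "common samples appear in different orders across layers; "
                "reorder the input matrices explicitly"
            )
    return MultiOmicsCollection(aligned)
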