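import numpy as np
import pytest

from jointnmf.preprocessing import MultiOmicsCollection, OmicsLayer


def make_layer(values, weight=1.0, name="lay", sample_prefix="S", feature_prefix="F"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsLayer(
        values=values,
        sample_ids=[f"{sample_prefix}{i+1}" for i in range(n)],
        feature_ids=[f"{name}_{feature_prefix}{j+1}" for j in range(p)],
        weight=weight,
        name=name,
    )


def make_collection(*matrices, weights=None):
    weights = weights or [1.0] * len(matrices)
    return MultiOmicsCollection(
        [make_layer(m, weight=w, name=f"lay{i+1}")
         for i, (m, w) in enumerate(zip(matrices, weights))]
    )


def block_basis(n, k, rng, fill_low=0.5, fill_high=1.0):
    """Non-negative block-structured basis: each sample loads on exactly one
    of k blocks of (near) equal size.  Returns (W0, truth labels)."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(1, k + 1), sizes)
    W0 = np.zeros((n, k))
    for j in range(n):
        W0[j, labels[j] - 1] = rng.uniform(fill_low, fill_high)
    return W0, labels


def exact_collection(n, k, layer_ps, rng):
    """Noiseless multi-layer data X^i = W0 H0^i with block-structured W0."""
    W0, labels = block_basis(n, k, rng)
    mats = []
    for p in layer_ps:
        H0 = rng.uniform(0.2, 1.0, size=(k, p))
        mats.append(W0 @ H0)
    return make_collection(*mats), labels, W0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_collection():
    """Two 4-sample layers with simple values."""
    return make_collection(
        [[1.0, 0.0, 2.0], [0.5, 1.0, 0.0], [0.0, 2.0, 1.0], [1.0, 1.0, 1.0]],
        [[0.2, 0.8], [0.4, 0.6], [0.9, 0.1], [0.5, 0.5]],
    )
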