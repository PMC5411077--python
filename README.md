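# jointnmf

Integrative clustering of multi-omics data by joint non-negative matrix
factorization.

Given `m` non-negative samples-by-features matrices `X^1 … X^m` measured on
the same `n` samples (e.g. expression, methylation, protein), `jointnmf`
estimates one shared basis matrix `W` (n × k) and layer-specific coefficient
matrices `H^i` (k × p_i) by minimizing the weighted objective

    Q = Σ_i θ^i ‖X^i − W H^i‖²_F ,   W ≥ 0, H^i ≥ 0,

with alternating exactly-solved non-negativity-constrained least squares
(a fast combinatorial multi-RHS active-set solver). Each sample's cluster is
the row-argmax of `W`. The package includes:

- **Preprocessing** — non-negative shift, unit-max rescale, SD /
  zero-proportion feature filters, data-driven layer weights
  (`θ^i = max_j meanSS_j / meanSS_i`).
- **Initialization** — deterministic NNDSVD (on the weighted concatenation
  of all layers) and seeded uniform starts; multi-start keeps the run with
  the smallest `Q`.
- **Model selection** — consensus matrices (iteration-averaged per run, or
  across-runs), average silhouette width on `1 − C̄`, cophenetic
  correlation, dispersion coefficient, RSS elbow, and a cross-validated
  Cluster Prediction Index (mean adjusted Rand index between test-set
  labels predicted from training coefficients and labels from clustering
  the test set independently).
- **Evaluation metrics** — adjusted Rand index, purity, normalized entropy.
- **Synthetic data** — a multi-layer generator with known cluster structure
  (cluster-specific Hadamard sign-pattern mean shifts on a configurable
  fraction of features, optional cross-layer latent coupling) plus the
  5 × 9 factorial grid of (true k, effect size) scenarios.

## Data orientation

All matrices are **samples in rows**: first CSV/TSV row = feature IDs,
first column = sample IDs. Much omics tooling stores features in rows —
transpose such files first. Layers are aligned by sample-ID intersection;
differing orders after alignment are an error, never silently reordered.

## CLI

```sh
# make a 3-cluster, 3-layer dataset with known truth
jointnmf simulate --k-true 3 --n 90 --p 60 --p 60 --p 60 \
    --effect-size 3.5 --seed 1 --out-dir data/

# factorize at fixed k
jointnmf fit --layer data/layer1.csv --layer data/layer2.csv \
    --layer data/layer3.csv --k 3 --n-init 30 --seed 1 --out-dir fit/
# -> fit/labels.tsv, W.csv, H_<layer>.csv, consensus.csv, metadata.json

# scan k and pick the optimum per measure
jointnmf select-k --layer data/layer1.csv --layer data/layer2.csv \
    --layer data/layer3.csv --k-min 2 --k-max 8 --measure all \
    --seed 1 --out-dir select/
# -> select/measures.tsv (tidy: measure, k, repetition, value), summary.json
```

Preprocessing flags: `--sd-min`, `--max-zero-prop` (strict `<`),
`--weights equal|auto|w1,w2,…`. Solver flags mirror the library defaults:
`--n-init 30 --tol 1e-4 --stability-count 50 --max-iter 200`. All
randomized paths are bit-reproducible given `--seed`.

## Python API sketch

```python
from jointnmf import (LayerSpec, SimulationSpec, simulate,
                      run_multistart, adjusted_rand_index)

sim = simulate(SimulationSpec(k_true=3, n=90,
                              layers=[LayerSpec(p=60)] * 3,
                              effect_size=3.5, seed=1))
best, runs = run_multistart(sim.collection, k=3, n_init=30, base_seed=1)
print(adjusted_rand_index(best.labels, sim.truth))
```

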