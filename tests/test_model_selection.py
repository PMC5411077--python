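import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from jointnmf.evaluation_metrics import adjusted_rand_index
from jointnmf.factorization import connectivity_matrix, run_multistart
from jointnmf.model_selection import (
    ConsensusMatrix,
    CPIConfig,
    KSelectionProfile,
    cluster_prediction_index,
    consensus_matrix,
    cophenetic_coefficient,
    dispersion_coefficient,
    predict_basis,
    rss,
    scan_k,
    select_k,
    silhouette_on_consensus,
)
from jointnmf.synthetic_data import LayerSpec, SimulationSpec, simulate

from .conftest import exact_collection, make_collection


def block_consensus(sizes):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return ConsensusMatrix(values=connectivity_matrix(labels).astype(float),
                           count=1), labels + 1


class TestConsensusMatrix:
    def test_mean_of_identical_histories(self):
        c = connectivity_matrix(np.array([1, 1, 2]))
        cbar = consensus_matrix([c, c, c])
        np.testing.assert_array_equal(cbar.values, c)

    def test_disagreement_gives_half(self):
        c1 = connectivity_matrix(np.array([1, 1, 2]))
        c2 = connectivity_matrix(np.array([1, 2, 2]))
        cbar = consensus_matrix([c1, c2])
        assert cbar.values[0, 1] == 0.5
        assert cbar.values[1, 2] == 0.5

    def test_diagonal_one(self, rng):
        hist = [connectivity_matrix(rng.integers(1, 4, size=6)) for _ in range(5)]
        cbar = consensus_matrix(hist)
        np.testing.assert_array_equal(np.diag(cbar.values), 1.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            ConsensusMatrix(values=np.array([[1.0, 0.2], [0.5, 1.0]]), count=1)
        with pytest.raises(ValueError, match="diagonal"):
            ConsensusMatrix(values=np.array([[0.5, 0.2], [0.2, 0.5]]), count=1)


class TestSilhouette:
    def test_perfect_blocks_give_one(self):
        cbar, labels = block_consensus([3, 3, 2])
        assert silhouette_on_consensus(cbar, labels) == pytest.approx(1.0)

    def test_all_half_gives_zero(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        cbar = ConsensusMatrix(values=v, count=1)
        assert silhouette_on_consensus(cbar, np.array([1, 1, 2, 2])) == pytest.approx(0.0)

    def test_hand_example(self):
        # 4 samples, clusters {0,1} and {2,3}; mixed consensus values
        v = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.3, 0.2],
                [0.2, 0.3, 1.0, 0.8],
                [0.1, 0.2, 0.8, 1.0],
            ]
        )
        cbar = ConsensusMatrix(values=v, count=1)
        labels = np.array([1, 1, 2, 2])
        d = 1.0 - v
        np.fill_diagonal(d, 0.0)
        expected = []
        for j, own, other in [(0, [1], [2, 3]), (1, [0], [2, 3]),
                              (2, [3], [0, 1]), (3, [2], [0, 1])]:
            a = np.mean([d[j, i] for i in own])
            b = np.mean([d[j, i] for i in other])
            expected.append((b - a) / max(a, b))
        assert silhouette_on_consensus(cbar, labels) == pytest.approx(np.mean(expected))

    def test_singleton_cluster_scores_zero(self):
        cbar, _ = block_consensus([1, 3])
        labels = np.array([1, 2, 2, 2])
        # singleton contributes 0; the rest are perfect
        assert silhouette_on_consensus(cbar, labels) == pytest.approx(3 / 4)

    def test_single_cluster_raises(self):
        cbar, _ = block_consensus([4])
        with pytest.raises(ValueError):
            silhouette_on_consensus(cbar, np.ones(4, dtype=int))


class TestCophenetic:
    def test_perfect_blocks_give_one(self):
        cbar, _ = block_consensus([3, 3, 2])
        assert cophenetic_coefficient(cbar) == pytest.approx(1.0)

    def test_perturbed_blocks_cross_checked(self):
        rng = np.random.default_rng(5)
        cbar0, _ = block_consensus([4, 4, 4])
        noise = rng.uniform(0, 0.05, size=(12, 12))
        noise = (noise + noise.T) / 2
        v = np.clip(cbar0.values - noise, 0, 1)
        np.fill_diagonal(v, 1.0)
        cbar = ConsensusMatrix(values=v, count=1)
        c = cophenetic_coefficient(cbar)
        assert 0.9 < c <= 1.0
        # independent cophenetic distances: walk the dendrogram merges
        d = cbar.distance()
        dm = squareform(d, checks=False)
        Z = sch.linkage(dm, method="average")
        n = 12
        members = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for idx, (a, b, height, _) in enumerate(Z):
            for i in members[int(a)]:
                for j in members[int(b)]:
                    coph[i, j] = coph[j, i] = height
            members[n + idx] = members.pop(int(a)) + members.pop(int(b))
        expected = np.corrcoef(dm, squareform(coph, checks=False))[0, 1]
        assert c == pytest.approx(expected, abs=1e-12)

    def test_constant_distances_raise(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        with pytest.raises(ValueError, match="constant"):
            cophenetic_coefficient(ConsensusMatrix(values=v, count=1))


class TestDispersion:
    def test_binary_consensus_is_one(self):
        cbar, _ = block_consensus([2, 3])
        assert dispersion_coefficient(cbar) == 1.0

    def test_hand_example_half(self):
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert dispersion_coefficient(ConsensusMatrix(values=v, count=1)) == pytest.approx(0.5)

    def test_all_half_matrix_is_zero(self):
        # hypothetical matrix (violates the unit diagonal, so build directly)
        assert float(np.mean(4 * (np.full((3, 3), 0.5) - 0.5) ** 2)) == 0.0

    def test_permutation_invariant(self, rng):
        hist = [connectivity_matrix(rng.integers(1, 3, size=8)) for _ in range(6)]
        cbar = consensus_matrix(hist)
        perm = rng.permutation(8)
        permuted = ConsensusMatrix(values=cbar.values[np.ix_(perm, perm)], count=6)
        assert dispersion_coefficient(permuted) == pytest.approx(
            dispersion_coefficient(cbar)
        )


class TestRSS:
    def test_exact_factorization_zero(self, rng):
        coll, _, W0 = exact_collection(12, 2, [5, 4], rng)
        H = [np.linalg.lstsq(W0, lay.values, rcond=None)[0] for lay in coll.layers]
        assert rss(coll, W0, H) == pytest.approx(0.0, abs=1e-18)

    def test_zero_basis(self, rng):
        coll, _, _ = exact_collection(10, 2, [4], rng)
        total = sum((lay.values**2).sum() for lay in coll.layers)
        assert rss(coll, np.zeros((10, 2)), [np.zeros((2, 4))]) == pytest.approx(total)

    def test_equals_unit_weight_objective(self, rng):
        from jointnmf.factorization import objective

        coll, _, _ = exact_collection(10, 2, [4, 6], rng)
        W = np.abs(np.random.default_rng(0).normal(size=(10, 2)))
        H = [np.abs(np.random.default_rng(1).normal(size=(2, p))) for p in (4, 6)]
        assert rss(coll, W, H) == pytest.approx(
            objective(coll, W, H, theta=[1.0, 1.0])
        )


class TestSelectK:
    def test_argmax_rule(self):
        prof = KSelectionProfile(
            k_values=[2, 3, 4, 5],
            values={"cpi": np.array([[0.4, 0.9, 0.6, 0.5]])},
        )
        assert select_k(prof, "cpi") == 3

    def test_tie_goes_to_smaller_k(self):
        prof = KSelectionProfile(
            k_values=[2, 3, 4, 5],
            values={"silhouette": np.array([[0.1, 0.8, 0.8, 0.2]])},
        )
        assert select_k(prof, "silhouette") == 3

    def test_rss_elbow(self):
        prof = KSelectionProfile(
            k_values=[2, 3, 4, 5],
            values={"rss": np.array([[100.0, 40.0, 35.0, 33.0]])},
        )
        assert select_k(prof, "rss") == 3

    def test_rss_needs_three_ks(self):
        prof = KSelectionProfile(k_values=[2, 3], values={"rss": np.array([[2.0, 1.0]])})
        with pytest.raises(ValueError):
            select_k(prof, "rss")

    def test_missing_measure(self):
        prof = KSelectionProfile(k_values=[2, 3], values={})
        with pytest.raises(ValueError, match="missing"):
            select_k(prof, "cpi")


@pytest.fixture(scope="module")
def strong_sim():
    spec = SimulationSpec(
        k_true=3, n=60, layers=[LayerSpec(p=40)] * 2, effect_size=4.0, seed=77
    )
    return simulate(spec)


class TestCPI:
    def test_reproducible(self, strong_sim):
        cfg = CPIConfig(k_range=[2, 3], n_repeats=2, n_init_train=2,
                        n_init_test=2, base_seed=5)
        p1 = cluster_prediction_index(strong_sim.collection, cfg)
        p2 = cluster_prediction_index(strong_sim.collection, cfg)
        np.testing.assert_array_equal(p1.values["cpi"], p2.values["cpi"])

    def test_strong_signal_peaks_at_k_true(self, strong_sim):
        cfg = CPIConfig(k_range=[2, 3, 4], n_repeats=3, n_init_train=3,
                        n_init_test=3, base_seed=11)
        prof = cluster_prediction_index(strong_sim.collection, cfg)
        assert select_k(prof, "cpi") == 3
        assert prof.mean("cpi")[1] > 0.95

    def test_identical_partitions_unit_cpi(self, strong_sim):
        # at k_true with a strong signal, predicted == observed (up to label
        # names) on every repetition, so every repetition's ARI is 1
        cfg = CPIConfig(k_range=[3], n_repeats=3, n_init_train=3,
                        n_init_test=3, base_seed=2)
        prof = cluster_prediction_index(strong_sim.collection, cfg)
        np.testing.assert_allclose(prof.values["cpi"][:, 0], 1.0)

    def test_pure_noise_has_no_winner(self):
        spec = SimulationSpec(
            k_true=3, n=48, layers=[LayerSpec(p=30)] * 2, effect_size=0.0, seed=13
        )
        sim = simulate(spec)
        cfg = CPIConfig(k_range=[2, 3, 4], n_repeats=3, n_init_train=3,
                        n_init_test=3, base_seed=4)
        prof = cluster_prediction_index(sim.collection, cfg)
        assert np.nanmax(prof.mean("cpi")) < 0.6

    def test_predict_basis_recovers_training_structure(self, rng):
        coll, truth, _ = exact_collection(30, 3, [12], rng)
        best, _ = run_multistart(coll, 3, n_init=3, base_seed=0)
        W = predict_basis(coll, best.H)
        predicted = np.argmax(W, axis=1) + 1
        assert adjusted_rand_index(predicted, truth) == 1.0


class TestScanK:
    def test_profile_shapes_and_reproducibility(self, strong_sim):
        prof1, _ = scan_k(strong_sim.collection, [2, 3], n_init=3, base_seed=9)
        prof2, _ = scan_k(strong_sim.collection, [2, 3], n_init=3, base_seed=9)
        for m in ("silhouette", "cophenetic", "dispersion", "rss"):
            assert prof1.values[m].shape == (3, 2)
            np.testing.assert_array_equal(prof1.values[m], prof2.values[m])

    def test_consensus_modes_both_valid(self, strong_sim):
        prof_runs, _ = scan_k(strong_sim.collection, [3], n_init=3, base_seed=9,
                              consensus_mode="runs")
        assert np.isfinite(prof_runs.values["dispersion"]).all()
        with pytest.raises(ValueError):
            scan_k(strong_sim.collection, [3], n_init=2, consensus_mode="bogus")
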