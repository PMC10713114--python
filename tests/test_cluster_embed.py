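"""Guided semi-supervised clustering: training, kNN propagation,
binarization, collapse, and UMAP embedding."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from cytopipe import (
    BinaryPhenotype,
    Dataset,
    binarize_phenotypes,
    collapse_clusters,
    downsample_balanced,
    estimate_thresholds,
    guided_cluster,
    knn_assign,
    rescale,
    run_umap,
    simulate_dataset,
    train_hierarchical,
)
from cytopipe import benchmark_design
from cytopipe.cluster_embed import _tagged_matrix
from cytopipe.errors import InfeasibilityError, ParameterError

from conftest import make_sample


def blob_dataset(rng, centers, n_per=200, sd=0.05, sample_id="S1"):
    """One sample of well-separated Gaussian blobs in [0,1]^d, tagged."""
    blocks = [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    X = np.vstack(blocks)
    truth = np.repeat(np.arange(len(centers)), n_per)
    perm = rng.permutation(len(X))
    s = make_sample(X[perm], sample_id, labels=[f"M{i+1}" for i in range(X.shape[1])])
    s.set_tag("downsampled", np.ones(len(X), dtype=bool))
    return Dataset([s], {sample_id: "g"}), truth[perm]


class TestTrainHierarchical:
    def test_two_blobs_recovered_exactly(self, rng):
        ds, truth = blob_dataset(rng, [(0.1, 0.1), (0.9, 0.9)], n_per=500)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=0.2,
                                   k_init=2, seed=0)
        train_truth = truth[model.training_index]
        assert adjusted_rand_score(train_truth, model.training_labels) == 1.0

    def test_degenerate_cut_every_cell_own_cluster(self, rng):
        ds, _ = blob_dataset(rng, [(0.5, 0.5)], n_per=100)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=0.1,
                                   k_init=10, seed=0)
        assert len(np.unique(model.training_labels)) == 10
        # full degenerate: K_init == n_training
        model2 = train_hierarchical(ds, ["M1", "M2"], training_fraction=0.1,
                                    k_init=len(model.training_index), seed=0)
        assert len(np.unique(model2.training_labels)) == len(model2.training_index)

    def test_training_fraction_one_uses_all(self, rng):
        ds, _ = blob_dataset(rng, [(0.2, 0.2), (0.8, 0.8)], n_per=100)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=1.0,
                                   k_init=2, seed=0)
        assert len(model.training_index) == 200

    def test_too_small_training_set(self, rng):
        ds, _ = blob_dataset(rng, [(0.5, 0.5)], n_per=200)
        with pytest.raises(InfeasibilityError):
            train_hierarchical(ds, ["M1", "M2"], training_fraction=0.01, k_init=20)


def brute_force_knn(train_X, train_labels, query_X, k):
    """All-pairs distance majority vote; ties -> nearest neighbor's label."""
    out = np.empty(len(query_X), dtype=np.int64)
    for i, q in enumerate(query_X):
        d = np.sqrt(np.sum((train_X - q) ** 2, axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        lab = train_labels[nearest]
        counts = np.bincount(lab)
        winners = np.flatnonzero(counts == counts.max())
        out[i] = winners[0] if len(winners) == 1 else lab[0]
    return out


class TestKnnAssign:
    def test_matches_brute_force_oracle(self, rng):
        ds, _ = blob_dataset(rng, [(0.2, 0.2), (0.8, 0.2), (0.5, 0.8)], n_per=400)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=0.2,
                                   k_init=6, seed=1)
        labels = knn_assign(model, ds, k_nn=5)
        X, _ = _tagged_matrix(ds, ("M1", "M2"))
        query = np.setdiff1d(np.arange(len(X)), model.training_index)
        expected = brute_force_knn(X[model.training_index], model.training_labels,
                                   X[query], 5)
        np.testing.assert_array_equal(labels[query], expected)
        # training events keep their own labels
        np.testing.assert_array_equal(labels[model.training_index],
                                      model.training_labels)

    def test_query_identical_to_training_point(self, rng):
        ds, _ = blob_dataset(rng, [(0.2, 0.2), (0.8, 0.8)], n_per=50)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=1.0,
                                   k_init=2, seed=0)
        labels = knn_assign(model, ds, k_nn=1)
        np.testing.assert_array_equal(labels, model.training_labels)

    def test_k_exceeding_training_size(self, rng):
        ds, _ = blob_dataset(rng, [(0.5, 0.5)], n_per=200)
        model = train_hierarchical(ds, ["M1", "M2"], training_fraction=0.1,
                                   k_init=2, seed=0)
        with pytest.raises(ParameterError):
            knn_assign(model, ds, k_nn=100)


class TestBinarize:
    def test_majority_fraction_sets_bit(self):
        X = np.array([[0.9]] * 9 + [[0.1]])
        phenos = binarize_phenotypes(X, np.ones(10, int), ["CD25"], {"CD25": 0.5})
        assert phenos[1].bits["CD25"] == 1
        assert phenos[1].derivation["CD25"] == pytest.approx(0.9)

    def test_exactly_half_is_negative(self):
        X = np.array([[0.9]] * 5 + [[0.1]] * 5)
        phenos = binarize_phenotypes(X, np.ones(10, int), ["CD25"], {"CD25": 0.5})
        assert phenos[1].bits["CD25"] == 0  # strict > 0.5

    def test_all_below(self):
        X = np.full((4, 1), 0.1)
        phenos = binarize_phenotypes(X, np.ones(4, int), ["CD25"], {"CD25": 0.5})
        assert phenos[1].bits["CD25"] == 0

    def test_missing_threshold(self):
        with pytest.raises(ParameterError):
            binarize_phenotypes(np.zeros((2, 1)), np.ones(2, int), ["CD3"], {})


def pheno(bits, n=10):
    channels = [f"M{i+1}" for i in range(len(bits))]
    return BinaryPhenotype(
        bits={c: b for c, b in zip(channels, bits)},
        derivation={c: 0.9 if b else 0.1 for c, b in zip(channels, bits)},
    )


class TestCollapse:
    def test_identical_phenotypes_merge(self):
        phenos = {1: pheno([0, 1, 1, 0]), 2: pheno([0, 1, 1, 0]), 3: pheno([1, 0, 0, 1])}
        cmap, final = collapse_clusters(phenos, k_max=10)
        assert len(final) == 2
        assert cmap[1] == cmap[2] != cmap[3]

    def test_no_stage2_when_under_kmax(self):
        phenos = {i + 1: pheno(bits) for i, bits in
                  enumerate([(0, 0), (0, 1), (1, 0), (1, 1)])}
        cmap, final = collapse_clusters(phenos, k_max=4)
        assert len(final) == 4
        assert len(set(cmap.values())) == 4

    def test_smallest_hamming_merges_first(self):
        phenos = {1: pheno([0, 0, 0, 0]), 2: pheno([0, 0, 0, 1]), 3: pheno([1, 1, 1, 1])}
        cmap, final = collapse_clusters(phenos, k_max=2)
        assert cmap[1] == cmap[2] != cmap[3]  # Hamming-1 pair merges

    def test_exhaustive_pair_oracle_first_merge(self, rng):
        # the first stage-2 merge must be the globally minimal pair per
        # the (hamming, min size, lowest ids) order
        for trial in range(10):
            k = int(rng.integers(4, 9))
            bit_patterns = set()
            while len(bit_patterns) < k:
                bit_patterns.add(tuple(rng.integers(0, 2, 5)))
            bit_patterns = sorted(bit_patterns)
            sizes = {i + 1: int(rng.integers(5, 100)) for i in range(k)}
            phenos = {i + 1: pheno(list(b)) for i, b in enumerate(bit_patterns)}
            cmap, _ = collapse_clusters(phenos, k_max=k - 1, sizes=sizes)
            merged_pairs = {}
            for init, fin in cmap.items():
                merged_pairs.setdefault(fin, []).append(init)
            merged = [v for v in merged_pairs.values() if len(v) > 1]
            assert len(merged) == 1
            got = tuple(sorted(merged[0]))
            best = min(
                (
                    (
                        sum(x != y for x, y in zip(bit_patterns[a - 1], bit_patterns[b - 1])),
                        min(sizes[a], sizes[b]),
                        a,
                        b,
                    )
                    for a, b in itertools.combinations(range(1, k + 1), 2)
                )
            )
            assert got == (best[2], best[3])

    def test_collapse_idempotent(self, rng):
        phenos = {i + 1: pheno(list(bits)) for i, bits in
                  enumerate(itertools.product([0, 1], repeat=3))}
        sizes = {i + 1: int(rng.integers(10, 50)) for i in range(8)}
        cmap, final = collapse_clusters(phenos, k_max=4, sizes=sizes)
        assert len(final) <= 4
        final_sizes = {}
        for init, fin in cmap.items():
            final_sizes[fin] = final_sizes.get(fin, 0) + sizes[init]
        cmap2, final2 = collapse_clusters(final, k_max=4, sizes=final_sizes)
        assert cmap2 == {i: i for i in final}  # renumbering already by size
        assert {c: p.bits for c, p in final2.items()} == \
               {c: p.bits for c, p in final.items()}

    def test_never_increases_cluster_count(self, rng):
        for _ in range(5):
            k = int(rng.integers(2, 10))
            phenos = {i + 1: pheno(rng.integers(0, 2, 4)) for i in range(k)}
            k_max = int(rng.integers(1, k + 1))
            _, final = collapse_clusters(phenos, k_max=k_max)
            assert len(final) <= min(k, k_max)


class TestEstimateThresholds:
    def test_bimodal_valley(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.05, 2000), rng.normal(0.8, 0.05, 2000)])
        s = make_sample(x.reshape(-1, 1), labels=["M1"])
        ds = Dataset([s], {"S1": "g"})
        thr = estimate_thresholds(ds, ["M1"])
        assert thr["M1"] == pytest.approx(0.5, abs=0.1)

    def test_unimodal_median(self, rng):
        x = rng.normal(0.5, 0.1, 3000)
        s = make_sample(x.reshape(-1, 1), labels=["M1"])
        ds = Dataset([s], {"S1": "g"})
        thr = estimate_thresholds(ds, ["M1"])
        assert thr["M1"] == pytest.approx(np.median(x), abs=1e-9)

    def test_override_wins(self, rng):
        s = make_sample(rng.normal(0.5, 0.1, (500, 1)), labels=["M1"])
        ds = Dataset([s], {"S1": "g"})
        thr = estimate_thresholds(ds, ["M1"], overrides={"M1": 0.42})
        assert thr["M1"] == 0.42


def test_guided_cluster_recovers_populations(rng):
    # small-scale version of the 8-population benchmark
    design = benchmark_design(seed=5, n_events=600, batch_shift=0.0)
    ds, truths = simulate_dataset(design)
    ds = rescale(downsample_balanced(ds, seed=5))
    tagged, labels, model, _ = guided_cluster(
        ds, ds.channel_labels, k_init=40, seed=5)
    truth = np.concatenate([
        truths[s.sample_id]["population"].to_numpy()[s.tags["downsampled"]]
        for s in ds.samples
    ])
    assert model.k_final == 8
    assert adjusted_rand_score(truth, labels) >= 0.90
    # every tagged event got exactly one final label
    assert np.all(labels >= 1)
    for s in tagged.samples:
        lab = s.tags["cluster"]
        np.testing.assert_array_equal(lab > 0, s.tags["downsampled"])


def test_guided_cluster_merges_indistinguishable_populations(rng):
    # two blobs identical on every thresholded channel end up in one
    # final cluster even if hierarchical clustering separates them
    X = np.vstack([rng.normal(0.75, 0.02, (300, 1)),
                   rng.normal(0.85, 0.02, (300, 1))])
    s = make_sample(X, labels=["M1"])
    s.set_tag("downsampled", np.ones(600, dtype=bool))
    ds = Dataset([s], {"S1": "g"})
    _, labels, model, _ = guided_cluster(
        ds, ["M1"], thresholds={"M1": 0.5}, k_init=4, training_fraction=0.5, seed=0)
    assert model.k_final == 1
    assert len(np.unique(labels)) == 1


class TestRunUmap:
    def test_three_blobs_separate(self, rng):
        centers = [(0.1, 0.1, 0.1, 0.1), (0.6, 0.6, 0.1, 0.1), (0.1, 0.6, 0.6, 0.6)]
        ds, truth = blob_dataset(rng, centers, n_per=100, sd=0.02)
        emb = run_umap(ds, ["M1", "M2", "M3", "M4"], seed=0)
        assert emb.coordinates.shape == (300, 2)
        assert np.all(np.isfinite(emb.coordinates))
        assert silhouette_score(emb.coordinates, truth) > 0.6

    def test_deterministic_given_seed(self, rng):
        ds, _ = blob_dataset(rng, [(0.2, 0.2), (0.8, 0.8)], n_per=60)
        a = run_umap(ds, ["M1", "M2"], seed=3)
        b = run_umap(ds, ["M1", "M2"], seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_too_few_events(self, rng):
        ds, _ = blob_dataset(rng, [(0.5, 0.5)], n_per=5)
        with pytest.raises(InfeasibilityError):
            run_umap(ds, ["M1", "M2"], {"n_neighbors": 15}, seed=0)
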