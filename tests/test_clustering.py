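"""Weighted Ward clustering, quality statistics, stability and naming."""
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from careseq import generate_cohort
from careseq.alphabet import TYPOLOGY_NAMES
from careseq.clustering import (
    bootstrap_stability,
    cluster_quality,
    cluster_sequences,
    cut_at,
    label_typologies,
    weighted_ward_cluster,
)
from careseq.sequences import CostScheme, build_sequences

CONSTANT = CostScheme.constant()


def _blocks(n_per=10, gap=50.0, rng=None):
    rng = rng or np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, n_per), rng.normal(gap, 1, n_per)])
    d = np.abs(x[:, None] - x[None, :])
    return d, np.repeat([1, 2], n_per)


def test_two_planted_blocks_recovered_exactly():
    d, truth = _blocks()
    labels = weighted_ward_cluster(d, np.ones(len(truth)), k=2).labels
    assert adjusted_rand_score(labels, truth) == 1.0


def test_partition_invariant_to_observation_order(rng):
    d, _ = _blocks(rng=rng)
    w = rng.uniform(0.5, 2.0, d.shape[0])
    base = weighted_ward_cluster(d, w, k=2).labels
    perm = rng.permutation(d.shape[0])
    permuted = weighted_ward_cluster(d[np.ix_(perm, perm)], w[perm], k=2).labels
    assert adjusted_rand_score(base[perm], permuted) == 1.0


def test_partition_invariant_to_uniform_weight_rescaling(rng):
    d = squareform(pdist(rng.normal(size=(40, 3))))
    w = rng.uniform(0.5, 2.0, 40)
    a = weighted_ward_cluster(d, w, k=4).labels
    b = weighted_ward_cluster(d, 17.3 * w, k=4).labels
    assert adjusted_rand_score(a, b) == 1.0


def test_equal_weights_match_classical_ward(rng):
    X = rng.normal(size=(80, 4))
    X[:40] += 3.5
    d = squareform(pdist(X))
    mine = weighted_ward_cluster(d, np.ones(80), k=3).labels
    ref = fcluster(linkage(X, method="ward"), t=3, criterion="maxclust")
    assert adjusted_rand_score(mine, ref) == 1.0


def test_integer_weights_match_replicated_sample(rng):
    """Mass-w observations must cluster exactly like w replicated copies."""
    for trial in range(10):
        X = rng.normal(size=(25, 2))
        w = rng.integers(1, 4, size=25)
        d = squareform(pdist(X))
        rep = np.repeat(np.arange(25), w)
        ref = fcluster(linkage(X[rep], method="ward"), t=3, criterion="maxclust")
        mine = weighted_ward_cluster(d, w.astype(float), k=3).labels
        assert adjusted_rand_score(np.repeat(mine, w), ref) == 1.0


def test_invalid_inputs_rejected():
    d = np.zeros((4, 4))
    with pytest.raises(ValueError, match="k="):
        weighted_ward_cluster(d, np.ones(4), k=9)
    with pytest.raises(ValueError, match="finite"):
        weighted_ward_cluster(np.full((3, 3), np.inf), np.ones(3), k=2)
    with pytest.raises(ValueError, match="positive"):
        weighted_ward_cluster(d, np.array([1, 1, 0, 1.0]), k=2)


def test_cut_at_recovers_nested_partitions(rng):
    d = squareform(pdist(rng.normal(size=(30, 2))))
    assign = weighted_ward_cluster(d, np.ones(30), k=6)
    for k in (2, 3, 6):
        lab = cut_at(assign, k)
        assert len(np.unique(lab)) == k
    # k-partition nests inside the (k-1)-partition
    l3, l2 = cut_at(assign, 3), cut_at(assign, 2)
    for c in np.unique(l3):
        assert len(np.unique(l2[l3 == c])) == 1


class TestQuality:
    def test_separated_blocks_have_silhouette_one(self):
        d = np.zeros((8, 8))
        d[:4, 4:] = 10.0
        d[4:, :4] = 10.0
        labels = np.repeat([1, 2], 4)
        q = cluster_quality(d, labels, np.ones(8))
        assert q["avg_silhouette_width"] == pytest.approx(1.0)
        assert q["between_within_r2"] == pytest.approx(1.0)

    def test_degenerate_identical_points_score_zero(self):
        d = np.zeros((6, 6))
        q = cluster_quality(d, np.repeat([1, 2], 3), np.ones(6))
        assert q["avg_silhouette_width"] == 0.0

    def test_equal_weight_silhouette_matches_sklearn(self, rng):
        X = rng.normal(size=(40, 3))
        X[:20] += 2.0
        d = squareform(pdist(X))
        labels = weighted_ward_cluster(d, np.ones(40), k=2).labels
        q = cluster_quality(d, labels, np.ones(40))
        ref = silhouette_score(d, labels, metric="precomputed")
        assert q["avg_silhouette_width"] == pytest.approx(ref, abs=1e-10)

    def test_random_distances_score_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = rng.uniform(1, 2, size=(50, 50))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = weighted_ward_cluster(d, np.ones(50), k=3).labels
            vals.append(cluster_quality(d, labels, np.ones(50))["avg_silhouette_width"])
        assert abs(np.mean(vals)) < 0.2


class TestStability:
    @staticmethod
    def _block_seqs(rng):
        states = np.vstack([
            np.tile([0, 0, 0, 0], (30, 1)),
            np.tile([4, 4, 4, 4], (30, 1)),
        ])
        from careseq.sequences import SequenceSet
        return SequenceSet(ids=np.arange(60), states=states, weights=np.ones(60))

    def test_perfectly_separated_blocks_are_fully_stable(self, rng):
        seqs = self._block_seqs(rng)
        stab = bootstrap_stability(seqs, CONSTANT, k=2, B=10, seed=1)
        assert all(v == pytest.approx(1.0) for v in stab.values())

    def test_single_resample_returns_unaveraged_jaccard(self, rng):
        seqs = self._block_seqs(rng)
        stab = bootstrap_stability(seqs, CONSTANT, k=2, B=1, seed=2)
        assert set(stab) == {1, 2}
        assert all(0.0 <= v <= 1.0 for v in stab.values())

    def test_default_cohort_typologies_are_stable(self, full_cohort):
        seqs = build_sequences(full_cohort)
        stab = bootstrap_stability(seqs, CONSTANT, k=4, B=20, seed=3)
        assert all(v > 0.6 for v in stab.values())


class TestNaming:
    def test_noiseless_cohort_gets_the_four_typology_names(self, default_params):
        p = default_params.copy()
        p.emission_noise = 0.0
        p.n_children = 600
        cohort = generate_cohort(p, seed=17)
        seqs = build_sequences(cohort)
        assign = cluster_sequences(seqs, CONSTANT, k=4)
        names = label_typologies(assign, seqs)
        assert set(names.values()) == set(TYPOLOGY_NAMES.values())
        # each named cluster coincides with its planted class
        named = assign.named_labels()
        for code, name in TYPOLOGY_NAMES.items():
            planted = list(TYPOLOGY_NAMES).index(code) + 1
            mask = cohort["latent_typology"].to_numpy() == planted
            assert (named[mask] == name).all()

    def test_k3_gets_generic_names(self, small_cohort):
        seqs = build_sequences(small_cohort)
        assign = cluster_sequences(seqs, CONSTANT, k=3)
        names = label_typologies(assign, seqs)
        assert set(names.values()) == {"cluster_1", "cluster_2", "cluster_3"}


def test_recovery_degrades_monotonically_in_emission_noise(default_params):
    aris = []
    for noise in (0.0, 0.1, 0.3):
        p = default_params.copy()
        p.emission_noise = noise
        p.n_children = 1500
        cohort = generate_cohort(p, seed=29)
        seqs = build_sequences(cohort)
        assign = cluster_sequences(seqs, CONSTANT, k=4)
        aris.append(adjusted_rand_score(assign.labels, cohort["latent_typology"]))
    assert aris[0] == pytest.approx(1.0)
    assert aris[0] > aris[1] > aris[2]
    assert aris[1] > 0.8
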