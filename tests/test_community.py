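"""Signed community detection against exact oracles; allegiance and co-occurrence."""

import numpy as np
import pytest

from dynfc.community import (CoOccurrence, Partition, co_occurrence,
                             detect_communities, detect_communities_stack,
                             partition_quality, reference_partition,
                             signed_modularity_matrix, window_allegiance)


def set_partitions(n):
    """All set partitions of range(n) as label arrays (Bell(6) = 203)."""
    if n == 1:
        yield [0]
        return
    for rest in set_partitions(n - 1):
        m = max(rest) + 1
        for c in range(m + 1):
            yield rest + [c]


def brute_force_optimum(w):
    """Exhaustive-enumeration oracle for the optimal Q*."""
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(w.shape[0]):
        q = partition_quality(w, np.asarray(labels))
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, np.asarray(best_labels)


def two_cliques(between=0.0):
    w = np.zeros((8, 8))
    w[:4, :4] = 1.0
    w[4:, 4:] = 1.0
    w[:4, 4:] = between
    w[4:, :4] = between
    np.fill_diagonal(w, 0.0)
    return w


class TestDetectCommunities:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_disconnected_cliques_recovered_exactly(self, seed):
        p = detect_communities(two_cliques(0.0), n_init=1, seed=seed)
        assert p.n_communities == 2
        assert len(set(p.labels[:4])) == 1 and len(set(p.labels[4:])) == 1

    def test_negative_between_weights_raise_quality(self):
        pos = two_cliques(0.0)
        neg = two_cliques(-0.5)
        p_pos = detect_communities(pos, n_init=10, seed=1)
        p_neg = detect_communities(neg, n_init=10, seed=1)
        assert np.array_equal(p_pos.labels, p_neg.labels)
        # same partition scores strictly higher once negatives penalize mixing
        assert p_neg.quality > partition_quality(pos, p_neg.labels)

    def test_quality_matches_enumeration_on_six_nodes(self, rng):
        w = rng.normal(0, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        best_q, _ = brute_force_optimum(w)
        p = detect_communities(w, n_init=100, seed=3)
        assert p.quality <= best_q + 1e-12
        assert abs(p.quality - best_q) < 1e-10

    def test_all_zero_matrix_single_community(self):
        p = detect_communities(np.zeros((5, 5)), n_init=5, seed=0)
        assert p.n_communities == 1 and p.quality == 0.0

    def test_returned_quality_is_max_over_inits(self):
        rng = np.random.default_rng(9)
        w = rng.normal(0, 1, (10, 10))
        w = (w + w.T) / 2
        best = detect_communities(w, n_init=50, seed=7)
        singles = [detect_communities(w, n_init=1, seed=s).quality for s in range(10)]
        assert best.quality >= max(singles) - 1e-12

    def test_node_permutation_equivariance(self, rng):
        w = rng.normal(0, 1, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        perm = rng.permutation(12)
        p = detect_communities(w, n_init=50, seed=2)
        pp = detect_communities(w[np.ix_(perm, perm)], n_init=50, seed=2)
        # same partition after undoing the permutation (up to label names)
        undone = np.empty(12, dtype=int)
        undone[perm] = pp.labels
        a = p.labels
        same_a = a[:, None] == a[None, :]
        same_b = undone[:, None] == undone[None, :]
        assert np.array_equal(same_a, same_b)

    def test_deterministic_given_seed(self, rng):
        w = rng.normal(0, 1, (15, 15))
        w = (w + w.T) / 2
        p1 = detect_communities(w, n_init=20, seed=5)
        p2 = detect_communities(w, n_init=20, seed=5)
        assert np.array_equal(p1.labels, p2.labels) and p1.quality == p2.quality

    def test_labels_contiguous_from_zero(self, rng):
        w = rng.normal(0, 1, (10, 10))
        w = (w + w.T) / 2
        p = detect_communities(w, n_init=10, seed=1)
        assert set(p.labels) == set(range(p.n_communities))


class TestReferencePartition:
    def test_recovers_planted_static_labels(self, cohort_run, cohort_spec):
        from sklearn.metrics import adjusted_rand_score
        ref = cohort_run.sessions[0].reference
        ari = adjusted_rand_score(cohort_spec.static_truth_labels(), ref.labels)
        assert ari >= 0.9

    def test_stack_detection_seeded_per_window(self, rng):
        stack = rng.normal(0, 1, (3, 8, 8))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        a = detect_communities_stack(stack, n_init=10, seed=4)
        b = detect_communities_stack(stack, n_init=10, seed=4)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.labels, pb.labels)


class TestAllegianceAndCoOccurrence:
    def test_allegiance_examples(self):
        p = Partition(np.array([0, 0, 1]), 0.0)
        a = window_allegiance(p)
        assert a[0, 1] == 1 and a[0, 2] == 0 and a[1, 2] == 0
        assert np.array_equal(np.diag(a), np.ones(3))
        ones = window_allegiance(Partition(np.zeros(4, dtype=int), 0.0))
        assert np.array_equal(ones, np.ones((4, 4)))
        eye = window_allegiance(Partition(np.arange(4), 0.0))
        assert np.array_equal(eye, np.eye(4))

    def test_two_window_hand_count(self):
        p1 = Partition(np.array([0, 0, 1]), 0.0)
        p2 = Partition(np.array([0, 0, 0]), 0.0)
        C = co_occurrence([p1, p2]).C
        assert C[0, 1] == 1.0 and C[0, 2] == 0.5 and C[1, 2] == 0.5

    def test_identical_windows_give_binary_matrix(self):
        p = Partition(np.array([0, 1, 0, 1]), 0.0)
        C = co_occurrence([p] * 7).C
        assert set(np.unique(C)) <= {0.0, 1.0}

    def test_entries_bounded_and_symmetric(self, rng):
        parts = [Partition(rng.integers(0, 3, 6), 0.0) for _ in range(9)]
        C = co_occurrence(parts).C
        assert (C >= 0).all() and (C <= 1).all()
        assert np.array_equal(C, C.T)

    def test_cooccurrence_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            CoOccurrence(np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="square"):
            CoOccurrence(np.ones((2, 3)))
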