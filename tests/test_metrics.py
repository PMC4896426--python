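"""Node-level dynamics metrics against hand-computed oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynfc.community import CoOccurrence, Partition
from dynfc.metrics import (aggregate_by_network, high_flex_cluster,
                           network_contrasts, session_overlap,
                           spatiotemporal_diversity, static_node_metrics,
                           temporal_flexibility, within_community_centrality)


def cooc(mat):
    mat = np.asarray(mat, dtype=float)
    np.fill_diagonal(mat, 1.0)
    return CoOccurrence(mat)


def random_cooc(rng, n):
    m = rng.uniform(0, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return CoOccurrence(m)


class TestFlexibility:
    def test_hand_example(self):
        # communities {0,1} and {2,3}; node 0 row (., 0.8, 0.3, 0.1)
        C = cooc([[1.0, 0.8, 0.3, 0.1],
                  [0.8, 1.0, 0.2, 0.2],
                  [0.3, 0.2, 1.0, 0.6],
                  [0.1, 0.2, 0.6, 1.0]])
        ref = Partition(np.array([0, 0, 1, 1]), 0.0)
        f = temporal_flexibility(C, ref)
        assert abs(f[0] - (0.4 / 1.2)) < 1e-12

    def test_extremes(self):
        C = cooc([[1, 0.9, 0.0], [0.9, 1, 0.0], [0.0, 0.0, 1]])
        ref = Partition(np.array([0, 0, 1]), 0.0)
        f = temporal_flexibility(C, ref)
        assert f[0] == 0.0  # only inside its community
        C2 = cooc([[1, 0.0, 0.7], [0.0, 1, 0.0], [0.7, 0.0, 1]])
        f2 = temporal_flexibility(C2, ref)
        assert f2[0] == 1.0  # only outside

    def test_zero_strength_flagged(self):
        C = cooc(np.zeros((3, 3)))
        ref = Partition(np.array([0, 0, 1]), 0.0)
        with pytest.warns(UserWarning):
            f = temporal_flexibility(C, ref)
        assert np.isnan(f).all()

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_flexibility_plus_within_fraction_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        C = random_cooc(rng, n)
        ref = Partition(rng.integers(0, 3, n), 0.0)
        f = temporal_flexibility(C, ref)
        mat = C.C.copy()
        np.fill_diagonal(mat, 0.0)
        for i in range(n):
            own = (ref.labels == ref.labels[i])
            own[i] = False
            within = mat[i, own].sum() / mat[i].sum()
            assert abs(f[i] + within - 1.0) < 1e-9


class TestDiversity:
    def test_binary_entropy_hand_value(self):
        # strengths (0.9, 0.3) over 2 communities -> p=(0.75,0.25)
        C = cooc([[1, 0.9, 0.3], [0.9, 1, 0.0], [0.3, 0.0, 1]])
        ref = Partition(np.array([0, 0, 1]), 0.0)
        h = spatiotemporal_diversity(C, ref)
        expect = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25)) / np.log(2)
        assert abs(h[0] - expect) < 1e-5
        assert abs(expect - 0.811278) < 1e-5

    def test_concentrated_strength_zero(self):
        C = cooc([[1, 0.8, 0.0], [0.8, 1, 0.0], [0.0, 0.0, 1]])
        ref = Partition(np.array([0, 0, 1]), 0.0)
        assert spatiotemporal_diversity(C, ref)[0] == 0.0

    def test_uniform_strength_maximal(self):
        C = cooc([[1, 0.5, 0.5], [0.5, 1, 0.0], [0.5, 0.0, 1]])
        ref = Partition(np.array([0, 1, 2]), 0.0)
        with np.errstate(all="ignore"):
            h = spatiotemporal_diversity(C, ref)
        assert abs(h[0] - np.log(2) / np.log(3)) < 1e-12  # 2 of 3 communities, even split

    def test_scale_invariance(self, rng):
        C = random_cooc(rng, 7)
        ref = Partition(rng.integers(0, 3, 7), 0.0)
        h1 = spatiotemporal_diversity(C, ref)
        h2 = spatiotemporal_diversity(CoOccurrence(np.clip(0.5 * C.C, 0, 1)), ref)
        off = ~np.isnan(h1)
        assert np.allclose(h1[off], h2[off], atol=1e-9)

    def test_single_community_rejected(self):
        C = cooc(np.full((3, 3), 0.5))
        with pytest.raises(ValueError):
            spatiotemporal_diversity(C, Partition(np.zeros(3, dtype=int), 0.0))


class TestCentrality:
    def test_hand_zscore(self):
        # one community of 3 with within strengths (0.5, 0.7, 0.9):
        # pairwise co-occurrences 0.15, 0.35, 0.55
        C = cooc([[1, 0.15, 0.35, 0.0], [0.15, 1, 0.55, 0.0], [0.35, 0.55, 1, 0.0],
                  [0.0, 0.0, 0.0, 1]])
        ref = Partition(np.array([0, 0, 0, 1]), 0.0)
        with pytest.warns(UserWarning):  # singleton community flagged
            z = within_community_centrality(C, ref)
        assert np.allclose(z[:3], [-1.0, 0.0, 1.0], atol=1e-9)  # sample sd = 0.2
        assert z[3] == 0.0

    def test_per_community_zero_sum(self, rng):
        C = random_cooc(rng, 9)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        z = within_community_centrality(C, Partition(labels, 0.0))
        for c in range(3):
            assert abs(z[labels == c].sum()) < 1e-9


class TestStaticMetrics:
    def test_uniform_participation(self):
        # node 0 evenly connected to 2 communities -> 1 - 1/2
        w = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]], dtype=float)
        ref = Partition(np.array([0, 0, 1]), 0.0)
        strength, part = static_node_metrics(w, ref)
        # node 0: s(comm0)=0.5 (node 1), s(comm1)=0.5 -> participation 0.5
        assert abs(part[0] - 0.5) < 1e-12

    def test_single_community_connection_zero_participation(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.8
        ref = Partition(np.array([0, 0, 1, 1]), 0.0)
        with pytest.warns(UserWarning):
            strength, part = static_node_metrics(w, ref)
        assert part[0] == 0.0
        assert strength[2] == 0.0 and np.isnan(part[2])

    def test_negative_weights_ignored(self, rng):
        w = -np.abs(rng.normal(0, 1, (4, 4)))
        w = (w + w.T) / 2
        ref = Partition(np.array([0, 0, 1, 1]), 0.0)
        with pytest.warns(UserWarning):
            strength, _ = static_node_metrics(w, ref)
        assert (strength == 0).all()


class TestHighFlexCluster:
    def make_table(self, f, h):
        nodes = [f"n{i}" for i in range(len(f))]
        return pd.DataFrame({"subject": "s0", "node": nodes,
                             "flexibility": f, "diversity": h})

    def test_separated_cluster_recovered(self):
        f = [0.1] * 8 + [0.8, 0.85]
        h = [0.3] * 8 + [0.9, 0.95]
        cluster, summary = high_flex_cluster(self.make_table(f, h), seed=0)
        assert set(cluster) == {"n8", "n9"}
        assert summary["high_flex"].sum() == 2

    def test_degenerate_plane_falls_back_to_threshold(self):
        with pytest.warns(UserWarning, match="threshold"):
            cluster, _ = high_flex_cluster(self.make_table([0.5] * 6, [0.5] * 6), seed=0)
        assert cluster == []  # nobody exceeds the percentile of a constant

    def test_invariant_to_axis_rescaling(self):
        rng = np.random.default_rng(3)
        f = np.r_[rng.uniform(0, 0.2, 10), rng.uniform(0.7, 0.9, 3)]
        h = np.r_[rng.uniform(0.2, 0.4, 10), rng.uniform(0.8, 1.0, 3)]
        c1, _ = high_flex_cluster(self.make_table(f, h), seed=1)
        c2, _ = high_flex_cluster(self.make_table(f * 100, h * 0.01), seed=1)
        assert set(c1) == set(c2)

    def test_threshold_variant(self):
        f = np.linspace(0, 1, 20)
        cluster, _ = high_flex_cluster(self.make_table(f, f), method="threshold",
                                       percentile=85.0)
        assert len(cluster) == 3  # top 15% of 20 nodes


class TestAggregation:
    def test_network_means_and_contrast(self, rng):
        rows = []
        for subj in range(12):
            for i in range(10):
                net = "SN" if i < 3 else "DMN"
                base = 0.7 if net == "SN" else 0.2
                rows.append({"subject": f"s{subj}", "node": f"n{i}", "network": net,
                             "flexibility": base + rng.normal(0, 0.02)})
        nd = pd.DataFrame(rows)
        per_net = aggregate_by_network(nd)
        assert per_net.shape == (12, 2)
        assert (per_net["SN"] > per_net["DMN"]).all()
        contrasts = network_contrasts(per_net)
        assert contrasts.loc[0, "p_holm"] < 0.001

    def test_node_order_irrelevant(self, rng):
        nd = pd.DataFrame({
            "subject": "s0", "node": [f"n{i}" for i in range(6)],
            "network": ["A", "B", "A", "B", "A", "B"],
            "flexibility": rng.uniform(0, 1, 6)})
        a = aggregate_by_network(nd)
        b = aggregate_by_network(nd.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a, b)


class TestSessionOverlap:
    def test_examples(self):
        assert session_overlap({1, 2, 3}, {1, 2, 3}) == (100.0, 100.0)
        assert session_overlap({1, 2}, {3, 4}) == (0.0, 0.0)
        a = set(range(1, 9))
        b = set(range(1, 7)) | {9, 10}
        assert session_overlap(a, b) == (75.0, 75.0)

    def test_empty_cluster_flagged(self):
        with pytest.warns(UserWarning):
            pa, pb = session_overlap(set(), {1})
        assert np.isnan(pa) and np.isnan(pb)
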