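"""Generator checks: planted correlation structure, determinism, behavior coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynfc.simulate import (BehaviorSpec, SimSpec, make_atlas, simulate_behavior,
                            simulate_cohort, simulate_subject)


def block_corr(mat, idx):
    c = np.corrcoef(mat[idx])
    return c[np.triu_indices(len(idx), 1)].mean()


class TestSimulateSubject:
    def test_realized_within_correlation_matches_target(self):
        spec = SimSpec(n_nodes=12, n_communities=3, community_sizes=(4, 4, 4),
                       n_frames=1200, within_corr=0.6, between_corr=0.0,
                       flexible_nodes=(), noise_sd=0.1, seed=1)
        x = simulate_subject(spec, 11)
        for block in (range(0, 4), range(4, 8), range(8, 12)):
            assert abs(block_corr(x, list(block)) - 0.6) < 0.1

    def test_degenerate_unit_correlation_gives_identical_series(self):
        spec = SimSpec(n_nodes=6, n_communities=2, community_sizes=(3, 3),
                       n_frames=50, within_corr=1.0, between_corr=0.0,
                       flexible_nodes=(), noise_sd=0.0, switch_period=25, seed=2)
        x = simulate_subject(spec, 3)
        assert np.array_equal(x[0], x[1]) and np.array_equal(x[1], x[2])
        assert np.array_equal(x[3], x[4]) and np.array_equal(x[4], x[5])

    def test_seeded_determinism(self):
        spec = SimSpec(seed=5, n_frames=300)
        assert np.array_equal(simulate_subject(spec, 9), simulate_subject(spec, 9))

    def test_within_exceeds_between(self):
        spec = SimSpec(n_frames=600, seed=3)
        x = simulate_subject(spec, 21)
        c = np.corrcoef(x)
        within = c[:12, :12][np.triu_indices(12, 1)]
        between = c[:12, 12:24].ravel()
        p = stats.mannwhitneyu(within, between, alternative="greater").pvalue
        assert p < 0.01

    def test_impossible_noise_compensated_target_rejected(self):
        with pytest.raises(ValueError, match="within_corr.*noise_sd"):
            SimSpec(within_corr=0.9, noise_sd=0.5)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError, match="community_sizes"):
            SimSpec(n_nodes=10, community_sizes=(4, 4))


class TestSimulateCohort:
    def test_sessions_share_nodes_but_not_sample_paths(self):
        spec = SimSpec(seed=4, n_frames=200)
        s1, s2 = simulate_cohort(spec, 3, sessions=2)
        assert s1.node_ids == s2.node_ids
        assert s1.subjects == s2.subjects
        assert not np.allclose(s1.data[0], s2.data[0])

    def test_regeneration_is_identical(self):
        spec = SimSpec(seed=4, n_frames=200)
        a = simulate_cohort(spec, 3, sessions=2)
        b = simulate_cohort(spec, 3, sessions=2)
        for sa, sb in zip(a, b):
            for ma, mb in zip(sa.data, sb.data):
                assert np.array_equal(ma, mb)

    def test_input_validation(self):
        spec = SimSpec(seed=1, n_frames=200)
        with pytest.raises(ValueError):
            simulate_cohort(spec, 1)
        with pytest.raises(ValueError):
            simulate_cohort(spec, 3, sessions=0)

    def test_atlas_covers_all_nodes_and_groups_flexible(self):
        spec = SimSpec(seed=1)
        atlas = make_atlas(spec)
        assert set(atlas["node_id"]) == set(spec.node_ids)
        flex_nets = atlas.set_index("node_id").loc[
            [f"n{i:03d}" for i in spec.flexible_nodes], "network_label"]
        assert (flex_nets == "SN").all()


class TestSimulateBehavior:
    def test_columns_exactly_standardized(self, rng):
        beh = simulate_behavior(BehaviorSpec(seed=1), rng.standard_normal(30))
        assert np.abs(beh.mean(axis=0)).max() < 1e-9
        assert np.abs(beh.std(axis=0, ddof=0) - 1).max() < 1e-9

    def test_null_coupling_centered_at_zero(self):
        # Monte-Carlo: with coupling_r=0 the composite-flexibility sample
        # correlation behaves like an ordinary null draw
        rng = np.random.default_rng(7)
        w = np.array([0.2, 1.0, 0.4])
        cs = []
        for rep in range(300):
            flex = rng.standard_normal(40)
            beh = simulate_behavior(BehaviorSpec(coupling_r=0.0, seed=rep), flex)
            cs.append(np.corrcoef(beh.to_numpy() @ w, flex)[0, 1])
        cs = np.asarray(cs)
        assert abs(cs.mean()) < 0.05
        band = 1.96 / np.sqrt(40)
        assert 0.85 < np.mean(np.abs(cs) < band) < 1.0

    def test_planted_coupling_recovered_on_average(self):
        rng = np.random.default_rng(8)
        w = np.array([0.2, 1.0, 0.4])
        cs = [
            np.corrcoef(
                simulate_behavior(BehaviorSpec(coupling_r=0.45, seed=rep),
                                  flex := rng.standard_normal(60)).to_numpy() @ w,
                flex)[0, 1]
            for rep in range(200)
        ]
        assert abs(np.mean(cs) - 0.45) < 0.03

    def test_full_coupling_without_residual_is_exact_affine(self, rng):
        flex = rng.standard_normal(25)
        beh = simulate_behavior(BehaviorSpec(coupling_r=1.0, residual=0.0, seed=3), flex)
        comp = beh.to_numpy() @ np.array([0.2, 1.0, 0.4])
        assert abs(np.corrcoef(comp, flex)[0, 1] - 1.0) < 1e-12

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer subjects"):
            simulate_behavior(BehaviorSpec(seed=1), rng.standard_normal(3))
        with pytest.raises(ValueError):
            simulate_behavior(BehaviorSpec(seed=1), rng.standard_normal(2))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BehaviorSpec(true_weights=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            BehaviorSpec(coupling_r=1.5)
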