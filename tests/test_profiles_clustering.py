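"""Degree profiles, joining/centering, PAM k-medoids and the gap statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kmernet.kmer_core import KmerVector, cpg_kmer_set, kmer_list
from kmernet.profiles_clustering import (
    annotate_clusters, cpg_enrichment_test, degree_profiles,
    gap_statistic_select, join_and_center, joint_profiles, kmedoids,
)


def _vectors(rows):
    """rows: (node_type, degree, counts)"""
    return [
        KmerVector(f"n{i}", t, d, np.asarray(c)) for i, (t, d, c) in enumerate(rows)
    ]


class TestDegreeProfiles:
    def test_mean_per_degree(self):
        vectors = _vectors([
            ("promoter", 3, [2] * 16),
            ("promoter", 3, [4] * 16),
        ])
        prof = degree_profiles(vectors, "promoter", 10)
        assert (prof.values[3] == 3.0).all()
        assert prof.n_nodes[3] == 2

    def test_unpopulated_degrees_are_nan(self):
        vectors = _vectors([("promoter", 1, [1] * 16)])
        prof = degree_profiles(vectors, "promoter", 5)
        assert prof.values[1].notna().all()
        assert prof.values[[2, 3, 4, 5]].isna().all().all()

    def test_matches_group_by_mean_oracle(self):
        rng = np.random.default_rng(6)
        rows = [
            ("enhancer", int(rng.integers(1, 6)), rng.integers(0, 9, 64))
            for _ in range(80)
        ]
        prof = degree_profiles(_vectors(rows), "enhancer", 6)
        for d in range(1, 7):
            group = [c for t, deg, c in rows if deg == d]
            if group:
                np.testing.assert_allclose(
                    prof.values[d].to_numpy(),
                    np.mean(group, axis=0), rtol=1e-12,
                )
            else:
                assert prof.values[d].isna().all()

    def test_degrees_above_cap_excluded(self):
        vectors = _vectors([("promoter", 99, [5] * 16), ("promoter", 1, [1] * 16)])
        prof = degree_profiles(vectors, "promoter", 10)
        assert prof.n_nodes.sum() == 1

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            degree_profiles(_vectors([("promoter", 1, [1] * 16)]), "promoter", 0)


class TestJoinAndCenter:
    def test_constant_profiles_center_to_zero(self):
        joint = join_and_center(np.full(10, 7.0), np.full(10, 7.0))
        np.testing.assert_allclose(joint, 0.0, atol=1e-12)

    def test_already_centered_input_unchanged(self):
        joint = join_and_center(np.ones(5), -np.ones(5))
        np.testing.assert_allclose(joint, np.concatenate([np.ones(5), -np.ones(5)]))

    def test_output_mean_always_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            joint = join_and_center(rng.random(10) * 9, rng.random(10) * 9)
            assert abs(joint.mean()) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            join_and_center(np.ones(5), np.ones(6))

    def test_joint_profiles_restricted_to_common_degrees(self):
        prom = degree_profiles(
            _vectors([("promoter", 1, [1] * 16), ("promoter", 2, [2] * 16)]),
            "promoter", 3,
        )
        enh = degree_profiles(
            _vectors([("enhancer", 1, [3] * 16), ("enhancer", 3, [4] * 16)]),
            "enhancer", 3,
        )
        joint, degrees = joint_profiles(prom, enh)
        assert degrees == [1]  # degree 2 empty for enhancers, 3 for promoters
        assert joint.shape == (16, 2)
        np.testing.assert_allclose(joint.to_numpy().mean(axis=1), 0.0, atol=1e-12)


class TestKmedoids:
    def test_k_equals_n_zero_cost(self):
        points = np.array([[0.0, 0], [5, 5], [9, 0]])
        result = kmedoids(points, 3, seed=0)
        assert result.cost == pytest.approx(0.0)
        assert sorted(result.medoid_indices) == [0, 1, 2]

    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, (20, 2))
        b = rng.normal(10, 0.3, (20, 2))
        points = np.vstack([a, b])
        result = kmedoids(points, 2, seed=0, restarts=5)
        labels = result.labels
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        points = rng.random((30, 4))
        r1 = kmedoids(points, 4, seed=99)
        r2 = kmedoids(points, 4, seed=99)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.medoid_indices, r2.medoid_indices)

    def test_medoids_are_data_points(self):
        rng = np.random.default_rng(1)
        points = rng.random((25, 3))
        result = kmedoids(points, 3, seed=2)
        for m in result.medoid_indices:
            assert 0 <= m < 25

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_medoid_search(self, k):
        """On <= 12 points the optimal medoid set is enumerable."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            points = rng.random((11, 2)) * 10
            best = np.inf
            for combo in itertools.combinations(range(11), k):
                diffs = points[:, None, :] - points[list(combo)][None, :, :]
                d = np.sqrt((diffs**2).sum(-1)).min(axis=1).sum()
                best = min(best, d)
            result = kmedoids(points, k, seed=3, restarts=40)
            assert result.cost == pytest.approx(best, rel=1e-9)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmedoids(np.zeros((3, 2)), 0)
        with pytest.raises(ValueError):
            kmedoids(np.zeros((3, 2)), 4)


class TestGapStatistic:
    @staticmethod
    def _three_clusters(rng, n_per=15):
        centers = np.array([[0.0, 0], [8, 8], [0, 9]])
        return np.vstack([
            rng.normal(c, 0.4, (n_per, 2)) for c in centers
        ])

    def test_recovers_three_separated_clusters(self):
        points = self._three_clusters(np.random.default_rng(0))
        result = gap_statistic_select(points, k_max=6, B=20, seed=0, restarts=5)
        assert result.k_selected == 3

    def test_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            points = self._three_clusters(np.random.default_rng(100 + seed))
            result = gap_statistic_select(points, k_max=6, B=10, seed=seed, restarts=4)
            hits += result.k_selected == 3
        assert hits >= 19  # >= 95% of 20 seeds

    def test_single_tight_cluster_selects_one(self):
        rng = np.random.default_rng(2)
        points = rng.normal(0, 1.0, (40, 2))
        result = gap_statistic_select(points, k_max=5, B=20, seed=1)
        assert result.k_selected == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        points = rng.random((30, 3))
        r1 = gap_statistic_select(points, k_max=4, B=10, seed=5)
        r2 = gap_statistic_select(points, k_max=4, B=10, seed=5)
        pd.testing.assert_frame_equal(r1.curve, r2.curve)
        assert r1.k_selected == r2.k_selected

    def test_k_max_clamped_to_points(self):
        rng = np.random.default_rng(4)
        result = gap_statistic_select(rng.random((5, 2)), k_max=10, B=10, seed=0)
        assert result.curve["k"].max() <= 4

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            gap_statistic_select(np.zeros((10, 2)), k_max=2, B=5)


class TestAnnotateClusters:
    @staticmethod
    def _joint(profiles: dict, degrees):
        return pd.DataFrame(
            {k: v - np.mean(v) for k, v in profiles.items()}
        ).T.set_axis(
            [f"P{d}" for d in degrees] + [f"E{d}" for d in degrees], axis=1
        )

    def test_all_cpg_cluster_fraction_one(self):
        degrees = [1, 2, 3, 4]
        up = np.array([1.0, 2, 3, 4] * 2)
        profiles = {"ACGT": up, "CGCG": up + 0.1, "TATA": -up}
        joint = self._joint(profiles, degrees)
        assignments = pd.Series([1, 1, 2], index=joint.index, name="cluster")
        summary = annotate_clusters(joint, assignments, cpg_kmer_set(4), degrees)
        row = summary.set_index("cluster").loc[1]
        assert row["cpg_fraction"] == pytest.approx(1.0)
        assert row["trend"] == "increasing"

    def test_flat_median_labelled_flat(self):
        degrees = [1, 2, 3, 4]
        flat = np.array([1.0, -1, 1, -1] * 2)
        joint = self._joint({"AAAA": flat, "TTTT": flat * 0.5}, degrees)
        assignments = pd.Series([1, 1], index=joint.index, name="cluster")
        summary = annotate_clusters(joint, assignments, cpg_kmer_set(4), degrees)
        assert summary.loc[0, "trend"] == "flat"

    def test_injected_trends_recovered(self):
        degrees = [1, 2, 3, 4, 5]
        rng = np.random.default_rng(0)
        inc = np.concatenate([np.arange(5.0), np.arange(5.0)])
        profiles = {}
        labels = {}
        for i, kmer in enumerate(kmer_list(4)[:30]):
            direction = 1 if i % 2 == 0 else -1
            profiles[kmer] = direction * inc + rng.normal(0, 0.05, 10)
            labels[kmer] = 1 if direction > 0 else 2
        joint = self._joint(profiles, degrees)
        assignments = pd.Series([labels[k] for k in joint.index], index=joint.index)
        summary = annotate_clusters(joint, assignments, cpg_kmer_set(4), degrees)
        trends = summary.set_index("cluster")["trend"]
        assert trends.loc[1] == "increasing"
        assert trends.loc[2] == "decreasing"

    def test_enrichment_requires_both_directions(self):
        summary = pd.DataFrame({
            "trend": ["increasing", "flat"], "n_cpg": [5, 0],
            "n_members": [10, 10],
        })
        with pytest.raises(ValueError):
            cpg_enrichment_test(summary)

    def test_enrichment_detects_concentrated_cpg(self):
        summary = pd.DataFrame({
            "trend": ["increasing", "decreasing"],
            "n_cpg": [40, 0], "n_members": [60, 60],
        })
        odds, p = cpg_enrichment_test(summary)
        assert p < 1e-10
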