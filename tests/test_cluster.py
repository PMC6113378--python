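import logging

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from devkin import (
    class_enrichment,
    classify_conservation,
    conservation_cutoff,
    kmeans_cluster,
)
from devkin.io import GeneClassLabels, OrthologMap
from devkin.timescale import normalized_profiles, project_onto_reference_grid
from oracles import exhaustive_min_inertia_partition, hypergeom_tail, partition_of, sorted_quantile


def _ids(n):
    return [f"g{i}" for i in range(n)]


class TestKmeansCluster:
    def test_two_bundles_match_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        bundle_a = rng.normal(0.0, 0.5, size=(4, 5))
        bundle_b = rng.normal(8.0, 0.5, size=(4, 5))
        profiles = np.vstack([bundle_a, bundle_b])
        result = kmeans_cluster(profiles, _ids(8), k=2, seed=1, n_restarts=20)
        oracle_partition, oracle_inertia = exhaustive_min_inertia_partition(profiles, 2)
        labels = np.array([result.assignments[g] for g in _ids(8)])
        assert partition_of(labels) == oracle_partition
        assert result.inertia == pytest.approx(oracle_inertia, rel=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_random_instances_match_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(8):
            n = int(rng.integers(max(k, 4), 9))
            profiles = rng.normal(size=(n, 4))
            result = kmeans_cluster(profiles, _ids(n), k=k, seed=7, n_restarts=40)
            oracle_partition, _ = exhaustive_min_inertia_partition(profiles, k)
            labels = np.array([result.assignments[g] for g in _ids(n)])
            assert partition_of(labels) == oracle_partition

    def test_k_equals_genes_zero_inertia(self):
        rng = np.random.default_rng(2)
        profiles = rng.normal(size=(6, 4))
        result = kmeans_cluster(profiles, _ids(6), k=6, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-18)
        assert sorted(result.assignments.values()) == list(range(6))

    def test_k_greater_than_genes_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            kmeans_cluster(np.ones((3, 2)), _ids(3), k=4)

    def test_archetype_recovery_on_synthetic_dataset(self, default_dataset):
        config, (matrix_a, _b, _omap, _labels, truth) = default_dataset
        env = truth[truth.gene_class == "environmental"]
        sub = matrix_a.subset(env.gene_id_a.tolist())
        profiles = normalized_profiles(sub)
        result = kmeans_cluster(profiles, sub.gene_ids, k=4, seed=3, n_restarts=20)
        found = [result.assignments[g] for g in sub.gene_ids]
        assert adjusted_rand_score(env.archetype_a.to_numpy(), found) >= 0.9

    def test_fixed_point_after_convergence(self):
        rng = np.random.default_rng(4)
        profiles = rng.normal(size=(30, 6))
        result = kmeans_cluster(profiles, _ids(30), k=4, seed=5)
        assert result.converged
        labels = np.array([result.assignments[g] for g in _ids(30)])
        d2 = ((profiles[:, None, :] - result.centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(np.argmin(d2, axis=1), labels)
        # each centroid is the mean of its members
        for j in range(4):
            members = profiles[labels == j]
            assert np.allclose(result.centroids[j], members.mean(axis=0), atol=1e-9)

    def test_inertia_non_increasing_within_restart(self):
        rng = np.random.default_rng(6)
        profiles = rng.normal(size=(50, 6))
        result = kmeans_cluster(profiles, _ids(50), k=5, seed=8, n_restarts=1)
        history = np.array(result.inertia_history)
        assert np.all(np.diff(history) <= 1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        profiles = rng.normal(size=(25, 5))
        r1 = kmeans_cluster(profiles, _ids(25), k=3, seed=42)
        r2 = kmeans_cluster(profiles, _ids(25), k=3, seed=42)
        assert r1.assignments == r2.assignments
        assert np.array_equal(r1.centroids, r2.centroids)


class TestConservationCutoff:
    def _result(self, profiles, k, **kw):
        return kmeans_cluster(profiles, _ids(len(profiles)), k=k, **kw)

    def test_members_on_centroid_cutoff_zero(self):
        profiles = np.vstack([np.zeros((3, 4)), np.ones((3, 4))])
        result = self._result(profiles, 2)
        assert conservation_cutoff(result, "max") == pytest.approx([0.0, 0.0])

    def test_max_rule_is_maximum_distance(self):
        # one cluster at 0 with members at distances 1, 2, 5 along first axis
        profiles = np.zeros((4, 4))
        profiles[1, 0], profiles[2, 0], profiles[3, 0] = 1.0, 2.0, 5.0
        result = self._result(profiles, 1)
        centroid_dist = np.linalg.norm(profiles - profiles.mean(axis=0), axis=1)
        assert conservation_cutoff(result, "max")[0] == pytest.approx(centroid_dist.max())

    def test_quantile_rule_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        profiles = rng.normal(size=(200, 5))
        result = self._result(profiles, 1)
        got = conservation_cutoff(result, "quantile:0.95")[0]
        assert got == pytest.approx(sorted_quantile(result.member_distances[0], 0.95))

    def test_global_max_rule(self):
        rng = np.random.default_rng(10)
        profiles = rng.normal(size=(40, 5))
        result = self._result(profiles, 3, seed=1)
        cutoffs = conservation_cutoff(result, "global-max")
        assert np.all(cutoffs == result.per_cluster_max_dist.max())

    def test_unknown_rule_is_error(self):
        profiles = np.random.default_rng(0).normal(size=(5, 3))
        result = self._result(profiles, 2)
        with pytest.raises(ValueError, match="unknown cutoff rule"):
            conservation_cutoff(result, "median-ish")


class TestClassifyConservation:
    def _setup(self, seed=0, n=24, k=3):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 5, size=(k, 5))
        profiles = np.vstack([centers[i % k] + rng.normal(0, 0.3, 5) for i in range(n)])
        ids_a = [f"a{i}" for i in range(n)]
        result = kmeans_cluster(profiles, ids_a, k=k, seed=1, n_restarts=20)
        return profiles, ids_a, result

    def test_identical_profile_conserved_both_methods(self):
        profiles, ids_a, result = self._setup()
        ids_b = [f"b{i}" for i in range(len(ids_a))]
        omap = OrthologMap(list(zip(ids_a, ids_b)))
        for method in ("distance", "membership"):
            calls = classify_conservation(result, profiles, ids_b, omap, method=method)
            assert len(calls) == len(ids_a)
            assert all(c.label == "conserved" for c in calls)

    def test_perturbation_just_past_cutoff_diverged(self):
        profiles, ids_a, result = self._setup()
        cutoffs = conservation_cutoff(result, "max")
        cluster0_gene = next(g for g, c in result.assignments.items() if c == 0)
        perturbed = result.centroids[0].copy()
        perturbed[2] += cutoffs[0] + 1.0
        calls = classify_conservation(
            result, perturbed[None, :], ["bX"], OrthologMap([(cluster0_gene, "bX")])
        )
        assert calls[0].label == "diverged"
        assert calls[0].distance == pytest.approx(cutoffs[0] + 1.0)

    def test_grid_mismatch_is_error(self):
        profiles, ids_a, result = self._setup()
        with pytest.raises(ValueError, match="grid mismatch"):
            classify_conservation(result, profiles[:, :3], ["b0"], OrthologMap([(ids_a[0], "b0")]))

    def test_self_comparison_all_conserved(self, default_dataset):
        config, (matrix_a, *_rest) = default_dataset
        profiles = normalized_profiles(matrix_a)
        result = kmeans_cluster(profiles, matrix_a.gene_ids, k=10, seed=17)
        omap = OrthologMap([(g, g) for g in matrix_a.gene_ids])
        calls = classify_conservation(result, profiles, matrix_a.gene_ids, omap)
        assert len(calls) == matrix_a.n_genes
        assert all(c.label == "conserved" for c in calls)

    def test_synthetic_dataset_conservation_rates(self, default_dataset):
        config, (matrix_a, matrix_b, omap, _labels, truth) = default_dataset
        profiles_a = normalized_profiles(matrix_a)
        result = kmeans_cluster(profiles_a, matrix_a.gene_ids, k=10, seed=17, n_restarts=20)
        profiles_b = project_onto_reference_grid(matrix_b, config.scaling, matrix_a.timepoints)
        calls = classify_conservation(result, profiles_b, matrix_b.gene_ids, omap)
        label_of = {c.ref_id: c.label for c in calls}
        truth = truth.assign(call=truth.gene_id_a.map(label_of))
        noise_only = truth[~truth.diverged]
        swapped = truth[truth.archetype_a != truth.archetype_b]
        assert (noise_only.call == "conserved").mean() >= 0.95
        assert (swapped.call == "diverged").mean() >= 0.90


class TestClassEnrichment:
    def test_extreme_enrichment_has_minimal_p(self):
        labels = GeneClassLabels(
            {f"g{i}": ("ribosomal" if i < 20 else "other") for i in range(100)}
        )
        background = [f"g{i}" for i in range(100)]
        target = [f"g{i}" for i in range(20)]  # exactly the ribosomal class
        table = class_enrichment(target, background, labels)
        assert table.iloc[0]["class"] == "ribosomal"
        assert table.iloc[0]["p_value"] == table["p_value"].min()

    def test_unlabelled_target_warns_and_returns_empty(self, caplog):
        labels = GeneClassLabels({"x1": "ribosomal"})
        with caplog.at_level(logging.WARNING):
            table = class_enrichment(["g1", "g2"], ["g1", "g2", "x1"], labels)
        assert table.empty
        assert any("no class labels" in rec.message for rec in caplog.records)

    def test_hypergeometric_matches_summation_oracle(self):
        # 10 in-class among target of 50; 20 in-class in background of 500
        labels = {}
        for i in range(500):
            labels[f"g{i}"] = "hit" if i < 20 else "rest"
        background = [f"g{i}" for i in range(500)]
        target = [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(100, 140)]
        table = class_enrichment(target, background, GeneClassLabels(labels))
        row = table[table["class"] == "hit"].iloc[0]
        assert row["n_target"] == 10
        assert row["p_value"] == pytest.approx(hypergeom_tail(10, 500, 20, 50), rel=1e-12)

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError, match="background"):
            class_enrichment(["g1"], [], GeneClassLabels({"g1": "x"}))

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(11)
        labels = {f"g{i}": f"class{i % 6}" for i in range(120)}
        background = list(labels)
        target = [f"g{i}" for i in rng.choice(120, size=30, replace=False)]
        table = class_enrichment(target, background, GeneClassLabels(labels))
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()
        assert (table["q_value"] <= 1.0 + 1e-15).all()
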