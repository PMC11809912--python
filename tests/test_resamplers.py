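import numpy as np
import pytest

from crnsmote import (
    CrnConfig,
    DbscanParams,
    LabeledDataset,
    adaptive_denoise_class,
    count_clusters,
    crn_smote,
    dbscan,
    enn_filter,
    partition_by_class,
    rn_smote,
    smote_enn,
    smote_tomek,
    tomek_links,
)
from conftest import random_dataset
from oracles import bfs_dbscan, brute_enn_keep, brute_tomek


def majority_rows(dataset):
    part = partition_by_class(dataset)
    return dataset.features[part.indices[part.majority]]


class TestAdaptiveDenoise:
    def test_tight_blob_stops_immediately(self, rng):
        samples = 0.5 + 0.005 * rng.standard_normal((50, 2))
        kept, eps, c, eps_traj, _ = adaptive_denoise_class(samples, CrnConfig(n_cluster=1))
        assert eps == pytest.approx(0.1)
        assert c == 1
        assert kept.shape == samples.shape
        assert eps_traj == (0.1,)

    def test_two_blobs_merged_under_single_cluster_bound(self, rng):
        blobs = np.vstack([
            0.02 * rng.standard_normal((20, 2)),
            [10.0, 0.0] + 0.02 * rng.standard_normal((20, 2)),
        ])
        cfg = CrnConfig(n_cluster=1, eps0=0.1, delta=0.5)
        kept, eps, c, _, _ = adaptive_denoise_class(blobs, cfg)
        assert c == 1
        assert kept.shape[0] == 40  # nothing removed once the gap is bridged
        assert eps > 10.0
        # independent check: the BFS oracle at the final radius agrees
        roles, clusters = bfs_dbscan(blobs, eps, cfg.min_samples)
        assert set(clusters) == {0}

    def test_two_blobs_kept_separate_with_bound_two(self, rng):
        blobs = np.vstack([
            0.02 * rng.standard_normal((20, 2)),
            [10.0, 0.0] + 0.02 * rng.standard_normal((20, 2)),
        ])
        kept, eps, c, _, _ = adaptive_denoise_class(blobs, CrnConfig(n_cluster=2))
        assert c == 2
        assert eps == pytest.approx(0.1)

    def test_eps_sequence_increases_by_delta(self, rng):
        blobs = np.vstack([
            0.02 * rng.standard_normal((15, 2)),
            [2.0, 0.0] + 0.02 * rng.standard_normal((15, 2)),
        ])
        cfg = CrnConfig(n_cluster=1, eps0=0.1, delta=0.05)
        _, _, _, eps_traj, _ = adaptive_denoise_class(blobs, cfg)
        diffs = np.diff(eps_traj)
        assert len(eps_traj) > 1
        np.testing.assert_allclose(diffs, cfg.delta)

    def test_small_class_passed_through_with_warning(self, caplog):
        samples = np.zeros((3, 2))
        with caplog.at_level("WARNING"):
            kept, eps, c, _, _ = adaptive_denoise_class(samples, CrnConfig(min_samples=5))
        assert eps is None and c is None
        np.testing.assert_array_equal(kept, samples)
        assert "unfiltered" in caplog.text


class TestCrnSmote:
    def test_balanced_clean_input_is_fixed_point(self, rng):
        features = np.vstack([
            0.01 * rng.standard_normal((20, 2)) + [0.2, 0.2],
            0.01 * rng.standard_normal((20, 2)) + [0.8, 0.8],
        ])
        ds = LabeledDataset(features=features, labels=np.array(["a"] * 20 + ["b"] * 20))
        result = crn_smote(ds, CrnConfig(n_cluster=1, seed=0))
        assert result.data.class_counts() == {"a": 20, "b": 20}
        assert all(a.n_removed == 0 for a in result.per_class.values())

    def test_final_counts_balanced_despite_removals(self, noisy_imbalanced):
        result = crn_smote(noisy_imbalanced, CrnConfig(n_cluster=1, seed=2))
        counts = result.data.class_counts()
        assert counts == {"maj": 120, "min": 120}

    def test_cluster_bound_satisfied_in_audit(self, noisy_imbalanced):
        for n_cluster in (1, 2):
            result = crn_smote(noisy_imbalanced, CrnConfig(n_cluster=n_cluster, seed=4))
            for audit in result.per_class.values():
                if audit.filtered:
                    assert 0 < audit.n_clusters <= n_cluster

    def test_majority_rows_unchanged(self, noisy_imbalanced):
        result = crn_smote(noisy_imbalanced, CrnConfig(n_cluster=1, seed=1))
        np.testing.assert_array_equal(
            majority_rows(result.data), majority_rows(noisy_imbalanced)
        )

    def test_three_class_audit_reports_single_cluster(self):
        from crnsmote import make_maternal_like

        ds = make_maternal_like(seed=0)
        result = crn_smote(ds, CrnConfig(n_cluster=1, seed=0))
        part = partition_by_class(ds)
        assert set(result.per_class) == set(part.minority_classes())
        for audit in result.per_class.values():
            assert audit.filtered
            assert audit.n_clusters == 1
        assert set(result.data.class_counts().values()) == {part.majority_count}

    def test_removed_noise_nested_within_small_eps_noise(self, noisy_imbalanced):
        """Points removed at the final (grown) radius are noise at eps0 too."""
        from crnsmote.smote import SmoteConfig, smote_balance

        cfg = CrnConfig(n_cluster=1, seed=5)
        balanced = smote_balance(
            noisy_imbalanced, SmoteConfig(k_neighbors=cfg.k_smote, seed=cfg.seed)
        )
        part = partition_by_class(noisy_imbalanced)
        for cls in part.minority_classes():
            matrix = balanced.class_matrix(cls)
            kept, eps, c, _, _ = adaptive_denoise_class(matrix, cfg)
            if eps is None:
                continue
            final_noise = {
                tuple(row) for row in matrix
            } - {tuple(row) for row in kept}
            small = dbscan(matrix, DbscanParams(eps=cfg.eps0, min_samples=cfg.min_samples))
            eps0_noise = {tuple(row) for row in matrix[small.noise_mask]}
            assert final_noise <= eps0_noise

    def test_deterministic(self, noisy_imbalanced):
        a = crn_smote(noisy_imbalanced, CrnConfig(seed=9))
        b = crn_smote(noisy_imbalanced, CrnConfig(seed=9))
        np.testing.assert_array_equal(a.data.features, b.data.features)

    def test_audit_dict_serializes(self, noisy_imbalanced):
        import json

        result = crn_smote(noisy_imbalanced, CrnConfig(seed=0))
        payload = json.loads(json.dumps(result.audit_dict()))
        assert payload["method"] == "1crn_smote"
        assert "min" in payload["per_class"]


class TestRnSmote:
    def test_balanced_clean_input_is_fixed_point(self, rng):
        features = np.vstack([
            0.01 * rng.standard_normal((20, 2)) + [0.2, 0.2],
            0.01 * rng.standard_normal((20, 2)) + [0.8, 0.8],
        ])
        ds = LabeledDataset(features=features, labels=np.array(["a"] * 20 + ["b"] * 20))
        result = rn_smote(ds, seed=0)
        assert result.data.class_counts() == {"a": 20, "b": 20}

    def test_keeps_every_cluster_without_constraint(self, two_blob_minority):
        """Unlike the constrained loop, a fixed small radius keeps both blobs."""
        result = rn_smote(
            two_blob_minority, dbscan_params=DbscanParams(eps=0.1, min_samples=5), seed=0
        )
        audit = result.per_class["min"]
        assert audit.n_clusters == 2
        kept = result.data.class_matrix("min")
        assert kept[:, 0].min() < 0.5 < kept[:, 0].max()  # both blobs survive

    def test_counts_balanced_to_majority(self, noisy_imbalanced):
        result = rn_smote(noisy_imbalanced, seed=1)
        assert set(result.data.class_counts().values()) == {120}

    def test_majority_rows_unchanged(self, noisy_imbalanced):
        result = rn_smote(noisy_imbalanced, seed=1)
        np.testing.assert_array_equal(
            majority_rows(result.data), majority_rows(noisy_imbalanced)
        )


class TestTomekLinks:
    def test_single_interleaved_pair(self):
        features = np.array([[0.0], [0.1], [5.0], [5.1], [10.0]])
        labels = np.array(["a", "b", "a", "a", "b"])
        ds = LabeledDataset(features=features, labels=labels)
        assert tomek_links(ds) == {(0, 1)}

    def test_separated_blobs_have_no_links(self, tiny_imbalanced):
        assert tomek_links(tiny_imbalanced) == set()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        ds = random_dataset(rng, n=40)
        assert tomek_links(ds) == brute_tomek(ds.features, list(ds.labels))

    def test_smote_tomek_removes_both_members(self, noisy_imbalanced):
        result = smote_tomek(noisy_imbalanced, seed=0)
        assert result.data.n_samples <= 240
        # removals recorded per class and symmetric under the "both" policy
        removed = [a.n_removed for a in result.per_class.values()]
        assert removed[0] == removed[1]

    def test_smote_tomek_majority_only_policy(self, noisy_imbalanced):
        result = smote_tomek(noisy_imbalanced, seed=0, removal="majority")
        assert result.per_class["min"].n_removed == 0


class TestEnn:
    def test_single_class_untouched(self, rng):
        ds = LabeledDataset(features=rng.random((10, 2)), labels=np.array(["a"] * 10))
        out = enn_filter(ds, k=3)
        assert out.n_samples == 10

    def test_mislabeled_point_removed(self, rng):
        features = np.vstack([
            0.01 * rng.standard_normal((12, 2)) + [0.2, 0.2],
            [[0.2, 0.2]],  # intruder sits in the middle of class a
            0.01 * rng.standard_normal((12, 2)) + [0.9, 0.9],
        ])
        labels = np.array(["a"] * 12 + ["b"] + ["b"] * 12)
        out = enn_filter(LabeledDataset(features=features, labels=labels), k=3)
        assert out.class_counts()["b"] == 12

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        ds = random_dataset(rng, n=35)
        keep = brute_enn_keep(ds.features, list(ds.labels), k=3)
        out = enn_filter(ds, k=3)
        expected = ds.features[np.asarray(keep)]
        np.testing.assert_array_equal(out.features, expected)

    def test_smote_enn_runs_and_records_removals(self, noisy_imbalanced):
        result = smote_enn(noisy_imbalanced, seed=0)
        assert result.method == "smote_enn"
        assert sum(a.n_removed for a in result.per_class.values()) == 240 - result.data.n_samples
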