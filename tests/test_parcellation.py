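from itertools import permutations
from math import comb

import numpy as np
import pytest

from hippoparc.covariance import voxel_parcel_covariance
from hippoparc.io import ParcelTable
from hippoparc.parcellation import (
    Parcellation,
    adjusted_rand_index,
    align_labels,
    bootstrap_consensus,
    consensus_mode,
    kmeans_profiles,
    percent_overlap,
    split_half_stability,
)
from hippoparc.synth import SyntheticConfig, generate_cohort


def ari_contingency_formula(a, b):
    """Hubert-Arabie ARI straight from the contingency-table formula."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    cats_a, cats_b = np.unique(a), np.unique(b)
    nij = np.array([[np.sum((a == i) & (b == j)) for j in cats_b] for i in cats_a])
    sum_ij = sum(comb(int(x), 2) for x in nij.ravel())
    sum_a = sum(comb(int(x), 2) for x in nij.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in nij.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == max_index else 0.0
    return (sum_ij - expected) / (max_index - expected)


def align_exhaustive(candidate, reference):
    """Best label permutation by brute force over all k! permutations."""
    k = int(candidate.max())
    best, best_agree = None, -1
    for perm in permutations(range(1, k + 1)):
        mapped = np.array([perm[c - 1] for c in candidate])
        agree = int((mapped == reference).sum())
        if agree > best_agree:
            best, best_agree = mapped, agree
    return best


class TestKmeansProfiles:
    def test_separated_clouds_match_nearest_centroid(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0] * 8, [50.0] * 8])
        X = np.vstack([c + rng.normal(0, 0.5, (20, 8)) for c in centers])
        labels = kmeans_profiles(X, k=2, restarts=20, seed=1)
        # brute-force check: every point is labeled with its nearest centroid
        cents = np.array([X[labels == j].mean(axis=0) for j in (1, 2)])
        nearest = 1 + np.argmin(
            ((X[:, None, :] - cents[None]) ** 2).sum(-1), axis=1
        )
        np.testing.assert_array_equal(labels, nearest)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_k_equals_one(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        assert set(kmeans_profiles(X, k=1, restarts=3, seed=0)) == {1}

    def test_duplicated_rows_share_labels(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 4)) * 10
        X = np.vstack([base, base])
        labels = kmeans_profiles(X, k=3, restarts=50, seed=3)
        np.testing.assert_array_equal(labels[:6], labels[6:])

    def test_k_exceeding_voxels_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(np.zeros((3, 2)), k=4, restarts=2, seed=0)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(4).normal(size=(30, 5))
        l1 = kmeans_profiles(X, k=3, restarts=10, seed=9)
        l2 = kmeans_profiles(X, k=3, restarts=10, seed=9)
        np.testing.assert_array_equal(l1, l2)

    def test_agrees_with_sklearn_on_separated_data(self):
        # independent route: sklearn's KMeans partition on well-separated data
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(5)
        centers = rng.normal(scale=20, size=(4, 6))
        X = np.vstack([c + rng.normal(0, 0.5, (15, 6)) for c in centers])
        ours = kmeans_profiles(X, k=4, restarts=30, seed=2)
        theirs = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(X)
        assert adjusted_rand_index(ours, theirs + 1) == pytest.approx(1.0)


class TestAlignLabels:
    def test_permutation_recovery_and_identity(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(1, 4, 30)
        perm = {1: 3, 2: 1, 3: 2}
        cand = np.array([perm[x] for x in ref])
        np.testing.assert_array_equal(align_labels(cand, ref), ref)
        np.testing.assert_array_equal(align_labels(ref, ref), ref)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_search(self, k):
        rng = np.random.default_rng(k)
        for trial in range(20):
            ref = rng.integers(1, k + 1, 40)
            cand = rng.integers(1, k + 1, 40)
            # ensure both use all k labels
            ref[:k] = cand[:k] = np.arange(1, k + 1)
            ours = align_labels(cand, ref)
            brute = align_exhaustive(cand, ref)
            assert (ours == ref).sum() == (brute == ref).sum()
            assert (ours == ref).sum() >= (cand == ref).sum()

    def test_differing_k_rejected(self):
        with pytest.raises(ValueError, match="differing k"):
            align_labels(np.array([1, 2, 3]), np.array([1, 2, 2]))


class TestConsensusMode:
    def test_idempotent_on_copies(self):
        labels = np.array([1, 2, 2, 3, 1])
        parc = consensus_mode([labels] * 7)
        np.testing.assert_array_equal(parc.labels, labels)

    def test_majority_and_tie_break(self):
        ens = [np.array([1, 1]), np.array([1, 2]), np.array([2, 2]), np.array([1, 2])]
        parc = consensus_mode(ens)
        assert parc.labels[0] == 1  # 3-1 majority
        assert parc.labels[1] == 2  # 3-1 majority
        tie = consensus_mode([np.array([1]), np.array([2])])
        assert tie.labels[0] == 1  # documented smallest-label tie-break

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            consensus_mode([])


class TestAdjustedRandIndex:
    def test_perfect_and_chance_level(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)
        assert adjusted_rand_index(a, np.ones(6)) == pytest.approx(0.0)

    def test_matches_contingency_formula(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 2, 2])
        assert adjusted_rand_index(a, b) == pytest.approx(
            ari_contingency_formula(a, b), abs=1e-10
        )
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.integers(1, 4, 20)
            b = rng.integers(1, 5, 20)
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_contingency_formula(a, b), abs=1e-10
            )

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 4, 50)
        b = rng.integers(1, 4, 50)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        relabeled = np.array([{1: 2, 2: 3, 3: 1}[x] for x in a])
        assert adjusted_rand_index(relabeled, b) == pytest.approx(
            adjusted_rand_index(a, b)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(np.array([1, 2]), np.array([1, 2, 3]))


class TestConsensusPipeline:
    def test_recovers_planted_clusters(self, small_cohort):
        cohort, truth = small_cohort
        parc = bootstrap_consensus(
            cohort.seed_matrix, cohort.parcel_table, k=3, n_boot=30, restarts=10, seed=5
        )
        assert adjusted_rand_index(parc.labels, truth.voxel_labels) >= 0.95

    def test_pipeline_determinism(self, small_cohort):
        cohort, _ = small_cohort
        p1 = bootstrap_consensus(
            cohort.seed_matrix, cohort.parcel_table, k=3, n_boot=10, restarts=5, seed=8
        )
        p2 = bootstrap_consensus(
            cohort.seed_matrix, cohort.parcel_table, k=3, n_boot=10, restarts=5, seed=8
        )
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_recovery_degrades_with_noise(self):
        aris = []
        for noise in (0.5, 4.0):
            cfg = SyntheticConfig(
                n_subjects=40, n_parcels=24, n_seed_voxels=60, k_true=3,
                noise_sd=noise, seed=21,
            )
            cohort, truth = generate_cohort(cfg)
            parc = bootstrap_consensus(
                cohort.seed_matrix, cohort.parcel_table, k=3, n_boot=20,
                restarts=10, seed=2,
            )
            aris.append(adjusted_rand_index(parc.labels, truth.voxel_labels))
        assert aris[1] < aris[0]


class TestSplitHalfStability:
    def test_duplicated_subjects_give_ari_one(self):
        # degenerate split: duplicating every subject makes halves identical
        # in distribution, so the recoverable k reproduces perfectly
        cfg = SyntheticConfig(
            n_subjects=30, n_parcels=24, n_seed_voxels=60, k_true=3,
            noise_sd=0.2, seed=13,
        )
        cohort, _ = generate_cohort(cfg)
        seed2 = np.vstack([cohort.seed_matrix, cohort.seed_matrix])
        table2 = ParcelTable(
            values=np.vstack([cohort.parcel_table.values, cohort.parcel_table.values]),
            subject_ids=[f"{s}{tag}" for tag in ("a", "b") for s in cohort.parcel_table.subject_ids],
            parcel_ids=cohort.parcel_table.parcel_ids,
        )
        curve = split_half_stability(
            seed2, table2, ks=[3], n_splits=5, n_boot_per_half=10, restarts=10, seed=3
        )
        assert curve.table.loc[3, "mean_ari"] >= 0.95

    def test_pure_noise_has_low_stability(self):
        cfg = SyntheticConfig(
            n_subjects=40, n_parcels=24, n_seed_voxels=60, k_true=3,
            loading=0.0, noise_sd=1.0, seed=17,
        )
        cohort, _ = generate_cohort(cfg)
        curve = split_half_stability(
            cohort.seed_matrix, cohort.parcel_table, ks=[2, 3, 4],
            n_splits=10, n_boot_per_half=10, restarts=5, seed=4,
        )
        assert (curve.table["mean_ari"] < 0.3).all()

    def test_planted_k_selected(self, small_cohort):
        cohort, _ = small_cohort
        curve = split_half_stability(
            cohort.seed_matrix, cohort.parcel_table, ks=[2, 3, 4],
            n_splits=15, n_boot_per_half=10, restarts=10, seed=6,
        )
        assert curve.selected_k == 3

    def test_too_few_subjects_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="at least 6"):
            split_half_stability(
                cohort.seed_matrix[:4], _subset_table(cohort.parcel_table, 4),
                ks=[2], n_splits=2, n_boot_per_half=5,
            )


def _subset_table(table, n):
    return ParcelTable(
        values=table.values[:n],
        subject_ids=table.subject_ids[:n],
        parcel_ids=table.parcel_ids,
    )


class TestPercentOverlap:
    def test_forced_arithmetic(self):
        parc = Parcellation(labels=np.array([1, 1, 1, 1, 2, 2]), k=2)
        ref = np.array([7, 7, 8, 8, 8, 8])
        table = percent_overlap(parc, ref)
        assert table.loc[1, 7] == pytest.approx(50.0)
        assert table.loc[1, 8] == pytest.approx(50.0)
        assert table.loc[2, 7] == pytest.approx(0.0)
        assert table.loc[2, 8] == pytest.approx(100.0)

    def test_rows_sum_to_at_most_100_with_disjoint_fields(self):
        rng = np.random.default_rng(3)
        parc = Parcellation(labels=rng.integers(1, 4, 100), k=3)
        ref = rng.integers(0, 3, 100)  # 0 = unlabeled
        table = percent_overlap(parc, ref)
        assert (table.sum(axis=1) <= 100.0 + 1e-9).all()

    def test_geometry_mismatch(self):
        parc = Parcellation(labels=np.array([1, 2]), k=2)
        with pytest.raises(ValueError, match="geometry"):
            percent_overlap(parc, np.array([1, 2, 3]))
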