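import math

import numpy as np
import pytest

from hievi.evaluation import (
    ami,
    ami_vs_eps,
    atlas_project,
    default_eps_grid,
    silhouette_scores,
    threshold_analysis,
)
from hievi.io_store import UNCLASSIFIED, AnnotationTable
from hievi.mpr import DistanceMatrix, pairwise_distances


def two_tight_pairs():
    """Two clusters of two points: within-distance 1, between-distance 100."""
    D = np.full((4, 4), 100.0)
    np.fill_diagonal(D, 0.0)
    D[0, 1] = D[1, 0] = 1.0
    D[2, 3] = D[3, 2] = 1.0
    return DistanceMatrix(["a", "b", "c", "d"], D)


class TestSilhouette:
    def test_two_tight_pairs_score_099_exactly(self):
        scores, mean = silhouette_scores(two_tight_pairs(), ["A", "A", "B", "B"])
        np.testing.assert_array_equal(scores, [0.99, 0.99, 0.99, 0.99])
        assert mean == 0.99

    def test_singleton_cluster_scores_zero(self):
        D = two_tight_pairs()
        scores, _ = silhouette_scores(D, ["A", "A", "B", "C"])
        assert scores[3] == 0.0 and scores[2] == 0.0

    def test_sentinel_samples_excluded(self):
        D5 = np.full((5, 5), 100.0)
        np.fill_diagonal(D5, 0.0)
        D5[0, 1] = D5[1, 0] = 1.0
        D5[2, 3] = D5[3, 2] = 1.0
        D = DistanceMatrix(list("abcde"), D5)
        scores, mean = silhouette_scores(D, ["A", "A", "B", "B", UNCLASSIFIED])
        assert scores.shape == (4,)
        assert mean == 0.99

    def test_matches_sklearn_when_no_singletons(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(5)
        mat = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(4, 1, (12, 4))])
        labels = ["A"] * 10 + ["B"] * 12
        D = pairwise_distances(mat, [f"G{i}" for i in range(22)])
        ours, _ = silhouette_scores(D, labels)
        theirs = silhouette_samples(D.D, labels, metric="precomputed")
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_informative_labels_beat_random_labels(self):
        rng = np.random.default_rng(6)
        mat = np.vstack([rng.normal(i * 3, 0.5, (8, 6)) for i in range(3)])
        names = [f"G{i}" for i in range(24)]
        D = pairwise_distances(mat, names)
        true = [f"C{i // 8}" for i in range(24)]
        random_labels = [true[i] for i in rng.permutation(24)]
        _, mean_true = silhouette_scores(D, true)
        _, mean_random = silhouette_scores(D, random_labels)
        assert mean_true > mean_random

    def test_single_label_is_an_error(self):
        with pytest.raises(ValueError):
            silhouette_scores(two_tight_pairs(), ["A", "A", "A", "A"])


def exact_emi_2x2(a, b, n):
    """Expected MI over the hypergeometric null for 2x2 margins (natural log)."""
    emi = 0.0
    for i in range(2):
        for j in range(2):
            lo = max(0, a[i] + b[j] - n)
            hi = min(a[i], b[j])
            for nij in range(lo, hi + 1):
                p = (
                    math.comb(b[j], nij)
                    * math.comb(n - b[j], a[i] - nij)
                    / math.comb(n, a[i])
                )
                if nij > 0:
                    emi += p * (nij / n) * math.log(n * nij / (a[i] * b[j]))
    return emi


class TestAMI:
    def test_permuted_labels_score_one(self):
        assert ami([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_identical_labelings_score_one(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 5, 60)
        assert ami(labels, labels) == pytest.approx(1.0)

    def test_cross_partition_matches_exact_hypergeometric_oracle(self):
        # [0,0,1,1] x [0,1,0,1]: MI = 0, so AMI = -EMI / (H - EMI)
        emi = exact_emi_2x2([2, 2], [2, 2], 4)
        h = math.log(2)  # both entropies are log 2; arithmetic mean = log 2
        expected = (0.0 - emi) / (h - emi)
        assert abs(ami([0, 0, 1, 1], [0, 1, 0, 1]) - expected) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ami([0, 1], [0, 1, 2])

    def test_random_labelings_score_near_zero(self):
        rng = np.random.default_rng(8)
        values = [
            ami(rng.integers(0, 5, 200), rng.integers(0, 5, 200)) for _ in range(100)
        ]
        assert abs(np.mean(values)) < 0.05

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.integers(0, 4, 50)
            b = rng.integers(0, 4, 50)
            v = ami(a, b)
            assert -1.0 <= v <= 1.0
            remap = rng.permutation(4)
            assert ami(remap[a], b) == pytest.approx(v, abs=1e-12)


class TestAMIvsEps:
    def test_genus_recovery_on_default_dataset(self, default_dataset):
        from hievi.mpr import pairwise_distances

        ds = default_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        profile = ami_vs_eps(D, ds.annotations, "genus")
        assert profile.max_ami >= 0.9
        assert profile.n_evaluated == len(ds.accessions)

    def test_eps_zero_grid_all_noise_ami_zero(self, small_dataset):
        from hievi.mpr import pairwise_distances

        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        profile = ami_vs_eps(D, ds.annotations, "genus", eps_grid=[0.0])
        assert profile.ami[0] == pytest.approx(0.0, abs=1e-9)

    def test_coarsest_eps_single_cluster_ami_zero(self, small_dataset):
        from hievi.mpr import pairwise_distances

        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        profile = ami_vs_eps(D, ds.annotations, "genus", eps_grid=[D.D.max() * 2])
        assert profile.ami[0] == pytest.approx(0.0, abs=1e-9)

    def test_sentinel_genomes_do_not_change_the_profile(self, small_dataset):
        from hievi.mpr import DistanceMatrix, pairwise_distances

        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        grid = default_eps_grid(D, 16)
        base = ami_vs_eps(D, ds.annotations, "genus", grid)

        # append two genomes labeled with the sentinel, far away in space
        extra = np.vstack([ds.mpr_matrix, np.eye(ds.mpr_matrix.shape[1])[:2] * 3])
        names = ds.accessions + ["EXTRA1", "EXTRA2"]
        table = ds.annotations.table.copy()
        table.loc["EXTRA1"] = UNCLASSIFIED
        table.loc["EXTRA2"] = UNCLASSIFIED
        D2 = pairwise_distances(extra, names)
        augmented = ami_vs_eps(D2, AnnotationTable(table), "genus", grid)
        np.testing.assert_allclose(augmented.ami, base.ami, atol=1e-12)
        assert augmented.n_evaluated == base.n_evaluated

    def test_empty_grid_rejected(self, small_dataset):
        from hievi.mpr import pairwise_distances

        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        with pytest.raises(ValueError, match="empty"):
            ami_vs_eps(D, ds.annotations, "genus", eps_grid=[])


class TestThresholdAnalysis:
    def test_separable_design_perfect_gate(self):
        from hievi.synthetic import TaxonomyDesign, generate_dataset

        ds = generate_dataset(TaxonomyDesign.separable())
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        report = threshold_analysis(D, ds.annotations, "genus", seed=1)
        assert report.tpr == 1.0 and report.fpr == 0.0
        # the selected threshold lies strictly inside the within/between gap
        labels = np.asarray(
            ds.annotations.rank_labels("genus", D.accessions), dtype=object
        )
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(D.n, 1)
        assert D.D[iu][same[iu]].max() < report.best_threshold < D.D[iu][~same[iu]].min()

    def test_null_distributions_give_small_j(self):
        rng = np.random.default_rng(10)
        mat = rng.standard_normal((40, 6))
        names = [f"G{i}" for i in range(40)]
        # labels carry no distance information
        ann = AnnotationTable.from_records(
            {n: {"genus": f"G{i % 4}"} for i, n in enumerate(names)}
        )
        D = pairwise_distances(mat, names)
        report = threshold_analysis(D, ann, "genus", n_pairs=10_000, seed=11)
        assert abs(report.tpr - report.fpr) < 0.1

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        r1 = threshold_analysis(D, ds.annotations, "genus", seed=5)
        r2 = threshold_analysis(D, ds.annotations, "genus", seed=5)
        assert r1.best_threshold == r2.best_threshold
        np.testing.assert_array_equal(r1.within_distances, r2.within_distances)

    def test_tpr_fpr_recomputable_from_stored_pairs(self, small_dataset):
        ds = small_dataset
        D = pairwise_distances(ds.mpr_matrix, ds.accessions)
        r = threshold_analysis(D, ds.annotations, "genus", seed=2)
        assert r.tpr == (r.within_distances <= r.best_threshold).mean()
        assert r.fpr == (r.between_distances <= r.best_threshold).mean()

    def test_missing_pool_names_the_rank(self):
        ann = AnnotationTable.from_records(
            {"A": {"genus": "G1"}, "B": {"genus": "G1"}}
        )
        D = pairwise_distances(np.array([[0.0], [1.0]]), ["A", "B"])
        with pytest.raises(ValueError, match="genus"):
            threshold_analysis(D, ann, "genus")


class TestAtlas:
    def test_projection_shape_and_determinism(self, small_dataset):
        ds = small_dataset
        c1 = atlas_project(ds.mpr_matrix, ds.accessions, n_neighbors=10, seed=4)
        c2 = atlas_project(ds.mpr_matrix, ds.accessions, n_neighbors=10, seed=4)
        assert c1.coordinates.shape == (len(ds.accessions), 2)
        np.testing.assert_array_equal(c1.coordinates, c2.coordinates)
        assert c1.parameters["visualization_only"] is True

    def test_separated_families_stay_separated_in_2d(self, default_dataset):
        ds = default_dataset
        coords = atlas_project(ds.mpr_matrix, ds.accessions, seed=0).coordinates
        fam = ds.annotations.table.loc[ds.accessions, "family"].to_numpy()
        iu = np.triu_indices(len(fam), 1)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)[iu]
        same = (fam[:, None] == fam[None, :])[iu]
        assert d2[same].mean() < d2[~same].mean()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            atlas_project(np.zeros((10, 4)), [f"G{i}" for i in range(10)], n_neighbors=16)
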