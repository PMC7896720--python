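import numpy as np
import pytest
from scipy import stats
from sklearn.decomposition import PCA as SkPCA

from radqc import structure_analysis as sa
from radqc.containers import MISSING, GenotypeMatrix
from radqc.synthetic_data import GenoSimConfig, simulate_genotypes

from conftest import two_pop_matrix


class TestPca:
    def test_rank_one_structure_separates_fixed_groups(self):
        m = two_pop_matrix([[0] * 10] * 6, [[2] * 10] * 6)
        res = sa.pca(m)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = pc1[:6], pc1[6:]
        assert np.sign(a).tolist() == [np.sign(a[0])] * 6
        assert np.sign(b[0]) == -np.sign(a[0])
        assert a.std() == pytest.approx(0.0, abs=1e-9)
        assert b.std() == pytest.approx(0.0, abs=1e-9)

    def test_scores_sum_to_zero_per_component(self, random_matrix):
        res = sa.pca(random_matrix, n_components=3)
        np.testing.assert_allclose(res.scores.sum(axis=0), 0.0, atol=1e-8)

    def test_eigenvalues_non_increasing(self, random_matrix):
        res = sa.pca(random_matrix, n_components=5)
        ev = res.eigenvalues
        assert (np.diff(ev) <= 1e-12).all()

    def test_complete_matrix_matches_sklearn(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(15, 30)).astype(np.int8)
        m = GenotypeMatrix(
            individual_ids=[f"X_{i}" for i in range(15)],
            pop_labels=["X"] * 15,
            locus_ids=[f"L{j}" for j in range(30)],
            calls=calls,
        )
        res = sa.pca(m, n_components=2)
        ref = SkPCA(n_components=2).fit_transform(calls.astype(float))
        for k in range(2):
            ours = res.scores.iloc[:, k].to_numpy()
            sign = np.sign(ours @ ref[:, k]) or 1.0
            np.testing.assert_allclose(ours, sign * ref[:, k], atol=1e-8)

    def test_all_missing_locus_dropped_and_listed(self):
        m = two_pop_matrix(
            [[0, MISSING], [1, MISSING]], [[2, MISSING], [1, MISSING]]
        )
        res = sa.pca(m)
        assert res.dropped_loci == ["L1"]

    def test_mean_imputed_displacement_collapses_after_filter(self):
        # two panmictic pops (one with heavy per-locus dropout) plus two
        # diverged background pops: imputation pulls the dropout pop away
        # from its partner; the missingness filter restores the overlap
        from radqc import qc_filters as qf

        cfg = GenoSimConfig(
            n_pops=4, n_per_pop=25, n_loci=1500,
            target_fst=[0.0, 0.0, 0.08, 0.08],
            pop_dropout={0: (0.55, (0.5, 0.9))}, seed=23,
        )
        matrix, _, _ = simulate_genotypes(cfg)
        labels = np.array(matrix.pop_labels)
        pair = (labels == "POP1") | (labels == "POP2")

        res = sa.pca(matrix)
        before = sa.cluster_separation(
            sa.PCAResult(res.scores[pair], res.eigenvalues, res.locus_means, []),
            labels[pair],
        )
        filtered, _ = qf.apply_filters(
            matrix, qf.FilterSpec([qf.LocusMaxMissingInPop("POP1", 0.5)])
        )
        res2 = sa.pca(filtered)
        after = sa.cluster_separation(
            sa.PCAResult(res2.scores[pair], res2.eigenvalues, res2.locus_means, []),
            labels[pair],
        )
        assert before > 0.25
        assert after < 0.05


class TestFstDistribution:
    def test_identical_samples_fill_first_bin(self):
        # duplicating one sample gives zero frequency variance: every
        # per-locus estimate is <= 0, so all loci land in the lowest bin
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        m = two_pop_matrix(calls, calls)
        dist = sa.fst_distribution(m, "A", "B")
        assert (dist.values <= 0).all()
        assert dist.bins["0-0.05"] == dist.values.size
        assert sum(dist.bins.values()) == dist.values.size

    def test_bins_match_manual_histogram(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=300, n_per_pop=40, target_fst=0.05, seed=3)
        )
        dist = sa.fst_distribution(matrix, "POP1", "POP2")
        v = dist.values
        expected = [
            (v < 0.05).sum(),
            ((v >= 0.05) & (v < 0.1)).sum(),
            ((v >= 0.1) & (v < 0.15)).sum(),
            ((v >= 0.15) & (v < 0.2)).sum(),
            (v >= 0.2).sum(),
        ]
        assert list(dist.bins.values()) == expected

    def test_negative_estimates_counted_in_lowest_bin(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=500, n_per_pop=30, target_fst=0.0, seed=4)
        )
        dist = sa.fst_distribution(matrix, "POP1", "POP2")
        assert (dist.values < 0).any()  # panmixia produces negative estimates
        assert sum(dist.bins.values()) == dist.values.size

    def test_subsample_determinism_contract(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=200, n_per_pop=40, target_fst=0.02, seed=5)
        )
        d1 = sa.fst_distribution(matrix, "POP1", "POP2", subsample_n=30, seed=9)
        d2 = sa.fst_distribution(matrix, "POP1", "POP2", subsample_n=30, seed=9)
        d3 = sa.fst_distribution(matrix, "POP1", "POP2", subsample_n=30, seed=10)
        assert d1.bins == d2.bins
        np.testing.assert_array_equal(d1.values, d2.values)
        assert not np.array_equal(d1.values, d3.values)

    def test_subsample_larger_than_population_rejected(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=50, n_per_pop=10, seed=6)
        )
        with pytest.raises(ValueError, match="cannot subsample"):
            sa.fst_distribution(matrix, "POP1", "POP2", subsample_n=30, seed=0)

    def test_bins_invariant_to_row_and_column_order(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=150, n_per_pop=20, target_fst=0.05, seed=7)
        )
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(matrix.n_individuals)
        perm_cols = rng.permutation(matrix.n_loci)
        shuffled = matrix.take_individuals(perm_rows).take_loci(perm_cols)
        d1 = sa.fst_distribution(matrix, "POP1", "POP2")
        d2 = sa.fst_distribution(shuffled, "POP1", "POP2")
        assert d1.bins == d2.bins

    def test_equal_divergence_pairs_same_distribution(self):
        # two disjoint pairs with the same true F: after subsample
        # normalization their per-locus F_ST distributions agree (KS)
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_pops=4, n_per_pop=40, n_loci=2000,
                          target_fst=0.02, seed=8)
        )
        d_a = sa.fst_distribution(matrix, "POP1", "POP2", subsample_n=30, seed=1)
        d_b = sa.fst_distribution(matrix, "POP3", "POP4", subsample_n=30, seed=1)
        ks = stats.ks_2samp(d_a.values, d_b.values)
        assert ks.pvalue > 0.01
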