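import numpy as np
import pytest

from radqc import popgen_stats as ps
from radqc.containers import MISSING
from radqc.synthetic_data import GenoSimConfig, simulate_genotypes

from conftest import two_pop_matrix
from oracles import pooled_fis_oracle, wc_components_oracle


class TestMissingness:
    def test_fractions_by_hand(self):
        m = two_pop_matrix(
            [[0, 1, MISSING, MISSING], [0, 0, 0, 0]],
            [[1, MISSING, 1, 1], [2, 2, 2, MISSING]],
        )
        prof = ps.missingness(m)
        assert prof.per_individual.tolist() == [0.5, 0.0, 0.25, 0.25]
        assert prof.per_locus_by_pop.loc["A"].tolist() == [0, 0, 0.5, 0.5]

    def test_overall_is_weighted_mean_of_pop_fractions(self, random_matrix):
        prof = ps.missingness(random_matrix)
        sizes = np.array(
            [random_matrix.pop_mask(p).sum() for p in random_matrix.populations]
        )
        weighted = (
            prof.per_locus_by_pop.to_numpy() * sizes[:, None]
        ).sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(prof.per_locus.to_numpy(), weighted)


class TestWcPairStats:
    def test_fixed_difference_gives_fst_one(self):
        m = two_pop_matrix([[0]] * 30, [[2]] * 30)
        df = ps.wc_pair_stats(m, "A", "B")
        assert df["fst"].iloc[0] == pytest.approx(1.0)

    def test_all_heterozygotes_pooled_fis_minus_one(self):
        m = two_pop_matrix([[1]] * 10, [[1]] * 10)
        df = ps.wc_pair_stats(m, "A", "B")
        assert df["fis_pooled"].iloc[0] == pytest.approx(-1.0)

    def test_monomorphic_locus_flagged_undefined(self):
        m = two_pop_matrix([[0, 0]] * 5, [[0, 1]] * 5)
        df = ps.wc_pair_stats(m, "A", "B")
        assert not df["defined"].iloc[0]
        assert df["defined"].iloc[1]

    def test_underpowered_locus_excluded(self):
        # locus 0: pop B has a single genotyped individual
        m = two_pop_matrix(
            [[0], [1], [2]], [[1], [MISSING], [MISSING]]
        )
        df = ps.wc_pair_stats(m, "A", "B")
        assert not df["defined"].iloc[0]

    def test_matches_literal_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, size=2)
            a = rng.integers(0, 3, size=(n1, 1))
            b = rng.integers(0, 3, size=(n2, 1))
            if len(set(a.ravel()) | set(b.ravel())) == 1:
                continue
            m = two_pop_matrix(a, b)
            df = ps.wc_pair_stats(m, "A", "B")
            ora = wc_components_oracle(
                n1, a.mean() / 2, (a == 1).mean(), n2, b.mean() / 2, (b == 1).mean()
            )
            np.testing.assert_allclose(
                df[["a", "b", "c"]].iloc[0].to_numpy(), ora, atol=1e-12
            )

    def test_fis_sign_tracks_het_excess(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = rng.integers(5, 30, size=2)
            a = rng.integers(0, 3, size=(n1, 1))
            b = rng.integers(0, 3, size=(n2, 1))
            m = two_pop_matrix(a, b)
            df = ps.wc_pair_stats(m, "A", "B")
            fis = df["fis_pooled"].iloc[0]
            if not np.isfinite(fis):
                continue
            n = n1 + n2
            pooled = np.vstack([a, b])
            oracle = pooled_fis_oracle(n, pooled.mean() / 2, (pooled == 1).mean())
            assert fis == pytest.approx(oracle, abs=1e-12)


class TestMultilocusFst:
    def test_single_locus_equals_per_locus_value(self):
        m = two_pop_matrix([[0, 1]] * 10, [[2, 1]] * 10)
        df = ps.wc_pair_stats(m, "A", "B")
        assert ps.multilocus_fst(df.iloc[[0]]) == pytest.approx(df["fst"].iloc[0])

    def test_no_estimable_loci_returns_nan(self):
        m = two_pop_matrix([[0]] * 5, [[0]] * 5)
        df = ps.wc_pair_stats(m, "A", "B")
        assert np.isnan(ps.multilocus_fst(df))

    def test_ratio_of_sums_not_mean_of_ratios(self):
        m = two_pop_matrix([[0, 0, 1]] * 20, [[2, 1, 1]] * 20)
        df = ps.wc_pair_stats(m, "A", "B")
        ok = df["defined"]
        expected = df.loc[ok, "a"].sum() / df.loc[ok, ["a", "b", "c"]].sum().sum()
        assert ps.multilocus_fst(df) == pytest.approx(expected)


class TestExactTest:
    def test_balanced_table_p_one(self):
        # 5 hets per pop -> allele table [[5,5],[5,5]]
        m = two_pop_matrix([[1]] * 5, [[1]] * 5)
        per_locus, _ = ps.exact_differentiation_test(m, "A", "B")
        assert per_locus["p"].iloc[0] == pytest.approx(1.0)

    def test_fixed_difference_p_exact_enumeration_value(self):
        # 10 B alleles vs 0 in pop A; 0 vs 10 in pop B -> p = 2/C(20,10)
        m = two_pop_matrix([[2]] * 5, [[0]] * 5)
        per_locus, _ = ps.exact_differentiation_test(m, "A", "B")
        assert per_locus["p"].iloc[0] == pytest.approx(2 / 184756, rel=1e-9)

    def test_identical_samples_not_significant(self):
        calls = np.tile([0, 1, 2, 1, 0], (4, 1)).T  # 5 individuals x 4 loci
        m = two_pop_matrix(calls, calls)
        per_locus, combined = ps.exact_differentiation_test(m, "A", "B")
        assert (per_locus["p"] == 1.0).all()
        assert combined > 0.01

    def test_monomorphic_locus_p_one_and_excluded(self):
        m = two_pop_matrix([[0, 1]] * 5, [[0, 1]] * 5)
        per_locus, _ = ps.exact_differentiation_test(m, "A", "B")
        assert per_locus["p"].iloc[0] == 1.0
        assert not per_locus["combined"].iloc[0]
        assert per_locus["combined"].iloc[1]

    def test_pvalues_superuniform_under_null(self):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(n_loci=2000, n_per_pop=30, target_fst=0.0, seed=11)
        )
        per_locus, _ = ps.exact_differentiation_test(matrix, "POP1", "POP2")
        p = per_locus.loc[per_locus["combined"], "p"].to_numpy()
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / p.size)
        assert frac <= 0.05 + 3 * se


class TestPairwiseMatrix:
    def test_symmetric_content_and_flags(self, random_matrix):
        table = ps.pairwise_fst_matrix(random_matrix, alpha=0.01)
        assert set(zip(table["pop_a"], table["pop_b"])) == {("P0", "P1")}
        row = table.iloc[0]
        assert row["significant"] == (row["p"] < 0.01)
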