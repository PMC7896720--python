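import numpy as np
import pytest

from radqc import qc_filters as qf
from radqc.containers import MISSING, DepthTable, GenotypeMatrix
from radqc.synthetic_data import GenoSimConfig, simulate_genotypes

from conftest import two_pop_matrix
from oracles import hdplot_d_oracle


def matrix_with_missing_fractions(fracs, n_loci=20):
    """One population; individual i missing round(frac*n_loci) loci."""
    calls = np.ones((len(fracs), n_loci), dtype=np.int8)
    for i, f in enumerate(fracs):
        calls[i, : int(round(f * n_loci))] = MISSING
    return GenotypeMatrix(
        individual_ids=[f"A_{i:02d}" for i in range(len(fracs))],
        pop_labels=["A"] * len(fracs),
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
    )


class TestIndividualFilter:
    def test_hand_counted_survivors(self):
        m = matrix_with_missing_fractions([0.1, 0.2, 0.55, 0.6, 0.0])
        spec = qf.FilterSpec([qf.IndividualMaxMissing(0.5)])
        out, report = qf.apply_filters(m, spec)
        assert out.n_individuals == 3
        rec = report.records[0]
        assert sorted(rec.removed["id"]) == ["A_02", "A_03"]
        assert rec.n_individuals_before == 5
        assert rec.n_individuals_after == 3

    def test_removes_exactly_ground_truth_high_missing_individuals(self):
        cfg = GenoSimConfig(
            n_pops=2, n_per_pop=25, n_loci=400, target_fst=0.0,
            pop_dropout={0: (0.7, (0.8, 1.0))}, seed=13,
        )
        matrix, _, _ = simulate_genotypes(cfg)
        frac = (matrix.calls == MISSING).mean(axis=1)
        expected_removed = {
            matrix.individual_ids[i] for i in np.flatnonzero(frac > 0.5)
        }
        out, report = qf.apply_filters(
            matrix, qf.FilterSpec([qf.IndividualMaxMissing(0.5)])
        )
        assert set(report.records[0].removed["id"]) == expected_removed


class TestKofNRateFilter:
    def _eight_pop_matrix(self, missing_pops):
        pops = [f"P{k}" for k in range(8)]
        calls = np.ones((8 * 4, 1), dtype=np.int8)
        labels = [p for p in pops for _ in range(4)]
        for k in missing_pops:
            calls[4 * k : 4 * (k + 1), 0] = MISSING
        return GenotypeMatrix(
            individual_ids=[f"{p}_{i}" for p in pops for i in range(4)],
            pop_labels=labels,
            locus_ids=["L0"],
            calls=calls,
        )

    def test_locus_fully_missing_in_two_pops_survives_6_of_8(self):
        m = self._eight_pop_matrix(missing_pops=[6, 7])
        out, _ = qf.flawed_kofn_rate_filter(m, r=0.8, k=6, n=8)
        assert out.n_loci == 1

    def test_strict_all_pop_rule_removes_it(self):
        m = self._eight_pop_matrix(missing_pops=[6, 7])
        out, _ = qf.flawed_kofn_rate_filter(m, r=0.8, k=8, n=8)
        assert out.n_loci == 0

    def test_n_must_match_population_count(self):
        m = self._eight_pop_matrix(missing_pops=[])
        with pytest.raises(ValueError, match="8 populations"):
            qf.flawed_kofn_rate_filter(m, r=0.8, k=4, n=6)

    def test_dropout_loci_survive_k_of_n_but_not_strict(self):
        cfg = GenoSimConfig(
            n_pops=4, n_per_pop=15, n_loci=300, target_fst=0.0,
            pop_dropout={0: (0.3, (1.0, 1.0))}, seed=17,
        )
        matrix, _, truth = simulate_genotypes(cfg)
        drop = set(truth["pop_dropout"]["POP1"]["loci"])
        lenient, _ = qf.flawed_kofn_rate_filter(matrix, r=0.8, k=3, n=4)
        strict, _ = qf.flawed_kofn_rate_filter(matrix, r=0.8, k=4, n=4)
        kept_lenient = {matrix.locus_ids.index(l) for l in lenient.locus_ids}
        kept_strict = {matrix.locus_ids.index(l) for l in strict.locus_ids}
        assert drop <= kept_lenient
        assert not (drop & kept_strict)


class TestFisFilter:
    def test_removes_heterozygote_excess_loci_keeps_undefined(self):
        # locus 0: all het in both pops (F_IS = -1); locus 1 ordinary;
        # locus 2 monomorphic (undefined -> retained)
        m = two_pop_matrix(
            [[1, 0, 0], [1, 1, 0], [1, 2, 0]] * 4,
            [[1, 0, 0], [1, 1, 0], [1, 0, 0]] * 4,
        )
        spec = qf.FilterSpec([qf.FisMin("A", "B", -0.2)])
        out, report = qf.apply_filters(m, spec)
        assert out.locus_ids == ["L1", "L2"]
        assert any("undefined" in n for n in report.records[0].notes)

    def test_absent_population_rejected_before_mutation(self, random_matrix):
        spec = qf.FilterSpec([qf.FisMin("P0", "NOPE", 0.0)])
        with pytest.raises(KeyError, match="NOPE"):
            qf.apply_filters(random_matrix, spec)


class TestCascadeReport:
    def test_counts_telescope_and_reasons_unique(self, random_matrix):
        spec = qf.FilterSpec(
            [
                qf.IndividualMaxMissing(0.3),
                qf.LocusMinGenotypeRatePerPop(r=0.8, required_pops="all"),
                qf.FisMin("P0", "P1", -0.5),
            ]
        )
        out, report = qf.apply_filters(random_matrix, spec)
        recs = report.records
        for prev, nxt in zip(recs, recs[1:]):
            assert prev.n_individuals_after == nxt.n_individuals_before
            assert prev.n_loci_after == nxt.n_loci_before
        assert recs[-1].n_loci_after == out.n_loci
        removals = report.removals()
        assert removals["id"].is_unique

    def test_empty_result_is_flagged_not_fatal(self):
        m = matrix_with_missing_fractions([0.9, 0.9, 0.9])
        out, report = qf.apply_filters(
            m, qf.FilterSpec([qf.IndividualMaxMissing(0.5)])
        )
        assert out.n_individuals == 0
        assert any("empty matrix" in n for n in report.records[-1].notes)

    def test_spec_round_trips_through_dicts(self):
        dicts = [
            {"step": "individual_max_missing", "threshold": 0.5},
            {"step": "fis_min", "pop_a": "A", "pop_b": "B", "threshold": -0.2},
            {"step": "hdplot_band", "d_min": -5, "d_max": 5, "max_het": 0.6},
        ]
        spec = qf.FilterSpec.from_dicts(dicts)
        assert [s.name for s in spec.steps] == [
            "individual_max_missing", "fis_min", "hdplot_band",
        ]
        with pytest.raises(ValueError, match="unknown filter step"):
            qf.step_from_dict({"step": "nope"})


class TestHdplot:
    def _depths(self, matrix, rows):
        return DepthTable.from_arrays(
            [matrix.individual_ids[i] for i, _, _, _ in rows],
            [matrix.locus_ids[j] for _, j, _, _ in rows],
            [a for _, _, a, _ in rows],
            [b for _, _, _, b in rows],
        )

    def test_perfect_balance(self):
        m = two_pop_matrix([[1]], [[1]])
        d = self._depths(m, [(0, 0, 10, 10), (1, 0, 5, 5)])
        hd = qf.hdplot(m, d)
        assert hd["allele_ratio"].iloc[0] == pytest.approx(0.5)
        assert hd["D"].iloc[0] == pytest.approx(0.0)

    def test_skewed_reads_z_score(self):
        m = two_pop_matrix([[1]], [[1]])
        d = self._depths(m, [(0, 0, 20, 5), (1, 0, 10, 5)])
        hd = qf.hdplot(m, d)
        assert hd["allele_ratio"].iloc[0] == pytest.approx(0.75)
        assert hd["D"].iloc[0] == pytest.approx((30 - 20) / np.sqrt(10))
        assert hd["D"].iloc[0] == pytest.approx(
            hdplot_d_oracle([(20, 5), (10, 5)])
        )

    def test_zero_depth_heterozygote_excluded_and_counted(self):
        m = two_pop_matrix([[1]], [[1]])
        d = self._depths(m, [(0, 0, 0, 0), (1, 0, 6, 2)])
        hd = qf.hdplot(m, d)
        assert hd["n_het_zero_depth"].iloc[0] == 1
        assert hd["allele_ratio"].iloc[0] == pytest.approx(0.75)

    def test_locus_without_heterozygotes_undefined_and_retained(self):
        m = two_pop_matrix([[0, 1]], [[2, 1]])
        d = self._depths(m, [(0, 1, 5, 5), (1, 1, 5, 5)])
        hd = qf.hdplot(m, d)
        assert np.isnan(hd["D"].iloc[0])
        out, report = qf.apply_filters(
            m, qf.FilterSpec([qf.HdplotBand(-5, 5)]), depths=d
        )
        assert out.n_loci == 2
        assert any("retained" in n for n in report.records[0].notes)

    def test_band_step_requires_depths(self, random_matrix):
        with pytest.raises(ValueError, match="depth"):
            qf.apply_filters(
                random_matrix, qf.FilterSpec([qf.HdplotBand(-5, 5)])
            )

    def test_undersplit_loci_show_paralog_allele_ratio(self):
        cfg = GenoSimConfig(
            n_loci=800, n_per_pop=40, frac_undersplit=0.05, seed=19,
        )
        matrix, depths, truth = simulate_genotypes(cfg)
        hd = qf.hdplot(matrix, depths)
        under = np.array(truth["classes"]) == "undersplit"
        flipped = np.array(truth["polarity_flipped"])
        ratio = hd["allele_ratio"].to_numpy()
        # polarity-flipped loci mirror around 0.5
        ratio = np.where(flipped, 1 - ratio, ratio)
        assert np.nanmean(ratio[under]) == pytest.approx(0.75, abs=0.02)
        assert np.nanmean(ratio[~under]) == pytest.approx(0.5, abs=0.02)
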