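import numpy as np
import pytest

from radqc import genotype_io as gio
from radqc.containers import MISSING
from radqc.synthetic_data import GenoSimConfig, simulate_genotypes


class TestReadGenepop:
    def test_parses_fixture_dimensions_and_pops(self, genepop_file):
        m = gio.read_genepop(genepop_file)
        assert m.calls.shape == (4, 3)
        assert m.locus_ids == ["LocA", "LocB", "LocC"]
        assert m.populations == ["CHA03", "CHA15"]
        assert m.pop_labels == ["CHA03", "CHA03", "CHA15", "CHA15"]

    def test_allele_a_is_first_encountered_code(self, genepop_file):
        m = gio.read_genepop(genepop_file)
        # first individual: 0101 -> hom A, 0102 -> het, 0202 -> hom B?
        # at LocC the first code seen is "02", so 0202 is hom A there
        assert m.calls[0].tolist() == [0, 1, 0]
        assert m.allele_names[2] == ("02", "01")

    def test_all_zero_token_is_missing(self, genepop_file):
        m = gio.read_genepop(genepop_file)
        assert m.calls[1, 1] == MISSING

    def test_malformed_token_names_line_and_column(self, tmp_path):
        path = tmp_path / "bad.genepop"
        path.write_text("t\nL1\nL2\nPOP\nA_1 ,  0101 01xx\n")
        with pytest.raises(gio.GenepopParseError, match=r"bad.genepop:5.*L2"):
            gio.read_genepop(path)

    def test_wrong_token_width_rejected(self, tmp_path):
        path = tmp_path / "bad.genepop"
        path.write_text("t\nL1\nPOP\nA_1 ,  010101\n")
        with pytest.raises(gio.GenepopParseError, match="malformed genotype token"):
            gio.read_genepop(path, allele_digits=2)

    def test_third_allele_rejected_naming_locus(self, tmp_path):
        path = tmp_path / "tri.genepop"
        path.write_text("t\nL1\nPOP\nA_1 ,  0102\nA_2 ,  0103\n")
        with pytest.raises(gio.GenepopParseError, match="L1.*2 alleles"):
            gio.read_genepop(path)

    def test_three_digit_alleles(self, tmp_path):
        path = tmp_path / "three.genepop"
        path.write_text("t\nL1\nPOP\nA_1 ,  001002\nA_2 ,  000000\n")
        m = gio.read_genepop(path, allele_digits=3)
        assert m.calls[0, 0] == 1
        assert m.calls[1, 0] == MISSING


class TestWriteGenepop:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, seed):
        matrix, _, _ = simulate_genotypes(
            GenoSimConfig(
                n_pops=3,
                n_per_pop=6,
                n_loci=40,
                target_fst=0.05,
                base_missing_rate=0.15,
                frac_undersplit=0.05,
                frac_oversplit=0.05,
                seed=seed,
            )
        )
        path = tmp_path / "rt.genepop"
        gio.write_genepop(matrix, path)
        again = gio.read_genepop(path)
        assert again.equals(matrix)

    def test_missing_written_as_zero_token(self, tmp_path, genepop_file):
        m = gio.read_genepop(genepop_file)
        out = tmp_path / "out.genepop"
        gio.write_genepop(m, out)
        line = out.read_text().splitlines()[6]  # CHA03_002
        assert "0000" in line.split(",")[1]

    def test_empty_locus_matrix_rejected(self, genepop_file, tmp_path):
        m = gio.read_genepop(genepop_file).take_loci(np.array([], dtype=int))
        with pytest.raises(ValueError, match="no loci"):
            gio.write_genepop(m, tmp_path / "x.genepop")


class TestReadGrowthTable:
    def test_mapping_river_year_sex(self, growth_csv):
        data = gio.read_growth_table(growth_csv)
        t = data.table
        assert t.loc[0].tolist() == ["Takwa", "north", "historical", "female", 11, 500.0]
        assert t.loc[1, "history"] == "contemporary"
        assert t.loc[3, "sex"] == "male"
        assert set(t.loc[t["river"] != "Takwa", "location"]) == {"south"}

    def test_unknown_river_listed_in_error(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("river,year,sex,age,length\nUnknown,2002,F,3,200\n")
        with pytest.raises(ValueError, match="Unknown"):
            gio.read_growth_table(path)

    def test_unmapped_year_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("river,year,sex,age,length\nTakwa,1999,F,3,200\n")
        with pytest.raises(ValueError, match="1999"):
            gio.read_growth_table(path)

    def test_non_numeric_age_reports_row(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "river,year,sex,age,length\nTakwa,2002,F,3,200\nTakwa,2002,F,old,210\n"
        )
        with pytest.raises(ValueError, match=r"age at rows \[1\]"):
            gio.read_growth_table(path)

    def test_custom_column_map(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("R,Y,S,A,TL\nTakwa,2002,F,11,500\n")
        data = gio.read_growth_table(
            path,
            column_map={"river": "R", "year": "Y", "sex": "S", "age": "A",
                        "length": "TL"},
        )
        assert len(data) == 1
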