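import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pleioconj.sumstats import (ColumnMap, P_FLOOR, harmonize_pair, p_from_z,
                                read_sumstats, read_table, write_table,
                                _align_alleles, SumStatsTable, PairedStats)

from conftest import write_sumstats_file

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _table(rows, trait="t"):
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                     "effect_allele", "other_allele", "p", "z"])
    df["n"] = np.nan
    return SumStatsTable(df=df, trait=trait)


class TestRead:
    def test_identity_parse_sorted_by_position(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv", [
            ("rs3", 1, 300, "A", "G", 0.5),
            ("rs1", 1, 100, "C", "T", 0.01),
            ("rs2", 1, 200, "G", "A", 0.2),
        ])
        t = read_sumstats(path)
        assert list(t.df["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert t.log["n_dropped"] == 0

    def test_out_of_range_p_dropped_and_counted(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "A", "G", 1.5),
            ("rs2", 1, 200, "A", "G", 0.5),
        ])
        t = read_sumstats(path)
        assert list(t.df["variant_id"]) == ["rs2"]
        assert t.log["n_dropped"] == 1

    def test_z_only_p_filled_from_normal_cdf(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv",
                                   [("rs1", 1, 100, "A", "G", 1.96)],
                                   header="SNP CHR BP A1 A2 Z")
        t = read_sumstats(path, ColumnMap(p=None))
        expected = 2 * sps.norm.sf(1.96)  # 0.0500 to 4 d.p.
        assert t.df["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert round(t.df["p"].iloc[0], 4) == 0.0500

    def test_p_zero_clamped_to_floor(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv",
                                   [("rs1", 1, 100, "A", "G", 0.0)])
        t = read_sumstats(path)
        assert t.df["p"].iloc[0] == P_FLOOR
        assert t.log["n_p_clamped"] == 1

    def test_indels_and_multibase_alleles_excluded(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "AT", "A", 0.1),
            ("rs2", 1, 200, "A", "A", 0.1),
            ("rs3", 1, 300, "A", "G", 0.1),
        ])
        t = read_sumstats(path)
        assert list(t.df["variant_id"]) == ["rs3"]
        assert t.log["n_nonsnp_alleles"] == 2

    def test_duplicate_keeps_largest_n(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv", [
            ("rs1", 1, 100, "A", "G", 0.1, 1000),
            ("rs1", 1, 100, "A", "G", 0.2, 5000),
        ], header="SNP CHR BP A1 A2 P N")
        t = read_sumstats(path)
        assert len(t.df) == 1
        assert t.df["p"].iloc[0] == 0.2

    def test_missing_mapped_column_names_it(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv",
                                   [("rs1", 1, 100, "A", "G", 0.1)])
        with pytest.raises(ValueError, match="MARKER"):
            read_sumstats(path, ColumnMap(variant_id="MARKER"))

    def test_empty_after_filtering_raises(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv",
                                   [("rs1", 1, 100, "A", "G", 2.0)])
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(path)

    def test_inconsistent_p_and_z_resolved_from_z(self, tmp_path):
        path = write_sumstats_file(tmp_path / "a.tsv",
                                   [("rs1", 1, 100, "A", "G", 0.9, 1.96)],
                                   header="SNP CHR BP A1 A2 P Z")
        t = read_sumstats(path)
        assert t.df["p"].iloc[0] == pytest.approx(2 * sps.norm.sf(1.96), rel=1e-12)
        assert t.log["n_p_recomputed"] == 1


class TestHarmonize:
    def test_swapped_alleles_flip_z_sign(self):
        s1 = _table([("rs1", "1", 100, "A", "G", 0.0455, 2.0)])
        s2 = _table([("rs1", "1", 100, "G", "A", 0.0455, -2.0)])
        paired = harmonize_pair(s1, s2)
        assert paired.df["z1"].iloc[0] == 2.0
        assert paired.df["z2"].iloc[0] == 2.0

    def test_palindromic_snp_removed_when_requested(self):
        s1 = _table([("rs1", "1", 100, "A", "T", 0.1, 1.0),
                     ("rs2", "1", 200, "A", "G", 0.1, 1.0)])
        s2 = _table([("rs1", "1", 100, "A", "T", 0.1, 1.0),
                     ("rs2", "1", 200, "A", "G", 0.1, 1.0)])
        paired = harmonize_pair(s1, s2, drop_ambiguous=True)
        assert list(paired.df["variant_id"]) == ["rs2"]
        assert paired.log["n_palindromic_removed"] == 1
        kept = harmonize_pair(s1, s2, drop_ambiguous=False)
        assert len(kept) == 2

    @pytest.mark.parametrize("a1,a2", [(a, b) for a, b in
                                       itertools.permutations("ACGT", 2)
                                       if COMP[a] != b])
    def test_all_nonpalindromic_allele_configurations(self, a1, a2):
        """Every strand/swap arrangement aligns with the oracle-derived sign."""
        for b1, b2, want in [
            (a1, a2, 1), (a2, a1, -1),
            (COMP[a1], COMP[a2], 1), (COMP[a2], COMP[a1], -1),
        ]:
            assert _align_alleles(a1, a2, b1, b2) == want
            s1 = _table([("rs1", "1", 100, a1, a2, 0.0455, 2.0)])
            s2 = _table([("rs1", "1", 100, b1, b2, 0.0455, 2.0)])
            paired = harmonize_pair(s1, s2, drop_ambiguous=False)
            assert paired.df["z2"].iloc[0] == 2.0 * want

    def test_irreconcilable_alleles_removed(self):
        s1 = _table([("rs1", "1", 100, "A", "G", 0.1, 1.0)])
        s2 = _table([("rs1", "1", 100, "A", "C", 0.1, 1.0)])
        with pytest.raises(ValueError, match="no harmonizable"):
            harmonize_pair(s1, s2)

    def test_empty_intersection_raises(self):
        s1 = _table([("rs1", "1", 100, "A", "G", 0.1, 1.0)])
        s2 = _table([("rs2", "1", 100, "A", "G", 0.1, 1.0)])
        with pytest.raises(ValueError, match="empty intersection"):
            harmonize_pair(s1, s2)

    def test_symmetric_variant_sets_and_p1_untouched(self):
        rows1 = [("rs%d" % i, "1", 100 * i, "A", "G", 0.1 * i, 1.0)
                 for i in range(1, 6)]
        rows2 = [("rs%d" % i, "1", 100 * i, "G", "A", 0.05 * i, -1.0)
                 for i in range(2, 7)]
        s1, s2 = _table(rows1), _table(rows2)
        f = harmonize_pair(s1, s2)
        r = harmonize_pair(s2, s1)
        assert set(f.df["variant_id"]) == set(r.df["variant_id"])
        expect_p1 = {f"rs{i}": 0.1 * i for i in range(2, 6)}
        for vid, p1 in zip(f.df["variant_id"], f.df["p1"]):
            assert p1 == pytest.approx(expect_p1[vid], rel=1e-12)


class TestWrite:
    def test_round_trip_identity(self, tmp_path, random_paired):
        paired = random_paired(5, seed=3)
        path = tmp_path / "out.tsv"
        write_table(paired, path)
        back = read_table(path)
        assert list(back["variant_id"]) == list(paired.df["variant_id"])
        np.testing.assert_allclose(back["p1"], paired.df["p1"], rtol=1e-12)
        np.testing.assert_allclose(back["p2"], paired.df["p2"], rtol=1e-12)

    def test_empty_input_refused_no_file(self, tmp_path):
        path = tmp_path / "out.tsv"
        with pytest.raises(ValueError):
            write_table(pd.DataFrame(), path)
        assert not path.exists()

    def test_scientific_notation_value_survives(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs2076756"], "FDR": [2.44e-04]})
        path = tmp_path / "out.tsv"
        write_table(df, path)
        assert read_table(path)["FDR"].iloc[0] == 2.44e-04
        assert "e-04" in path.read_text().lower()
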