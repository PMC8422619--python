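import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from localcov import sumstats
from localcov.sumstats import (GenomePartition, SchemaError, assign_to_blocks,
                               harmonize_pair, qc_filter, read_partition,
                               read_sumstats, validate_partition)


def _write(tmp_path, text, name="ss.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_drops_missing_z_and_indel_alleles(self, tmp_path):
        path = _write(tmp_path, "\n".join([
            "SNP A1 A2 Z N",
            "rs1 A G 1.5 1000",
            "rs2 C T NA 1000",       # missing z
            "rs3 I D 0.3 1000",      # indel codes
            "rs4 T C -0.7 1000",
            "rs5 G A 2.2 1000",
        ]))
        df = read_sumstats(path)
        assert list(df["snp"]) == ["rs1", "rs4", "rs5"]
        assert df.attrs["drops"]["nonfinite_z_or_n"] == 1
        assert df.attrs["drops"]["invalid_alleles"] == 1

    def test_header_only_file_gives_empty_frame(self, tmp_path):
        df = read_sumstats(_write(tmp_path, "SNP A1 A2 Z N\n"))
        assert len(df) == 0

    def test_duplicate_snp_keeps_first(self, tmp_path):
        df = read_sumstats(_write(tmp_path, "\n".join([
            "SNP A1 A2 Z N", "rs1 A G 1.0 500", "rs1 A G 9.0 500"])))
        assert len(df) == 1 and df["z"].iloc[0] == 1.0
        assert df.attrs["drops"]["duplicate_snp"] == 1

    def test_missing_column_names_the_column(self, tmp_path):
        with pytest.raises(SchemaError, match="Z"):
            read_sumstats(_write(tmp_path, "SNP A1 A2 N\nrs1 A G 100\n"))


def _panel():
    return pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chrom": [1, 1, 6, 23, 2],
        "pos": [500, 900, 30_000_000, 100, 7000],
        "maf": [0.3, 0.04, 0.2, 0.3, 0.10],
    })


def _records(rows):
    df = pd.DataFrame(rows, columns=["snp", "a1", "a2", "z", "n"])
    df.attrs["n_median"] = float(df["n"].median())
    return df


class TestQCFilter:
    def test_filters_by_rule(self):
        df = _records([("rs1", "A", "T", 1.0, 100),   # strand-ambiguous
                       ("rs2", "A", "G", 1.0, 100),   # panel MAF 0.04 < 0.05
                       ("rs3", "A", "G", 1.0, 100),   # inside MHC window
                       ("rs4", "A", "G", 1.0, 100),   # chrom 23
                       ("rs5", "A", "G", 1.0, 100)])  # keeper
        out = qc_filter(df, _panel(), maf_min=0.05, exclude_mhc=True)
        assert list(out["snp"]) == ["rs5"]
        c = out.attrs["qc_counts"]
        assert (c["strand_ambiguous"], c["low_maf"], c["mhc"],
                c["non_autosomal"]) == (1, 1, 1, 1)

    def test_mhc_snps_survive_when_filter_off(self):
        df = _records([("rs3", "A", "G", 1.0, 100)])
        out = qc_filter(df, _panel(), exclude_mhc=False)
        assert list(out["snp"]) == ["rs3"]


def _qcd(rows):
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2", "z"])
    df["n"] = 1000
    df.attrs["n_median"] = 1000.0
    return df


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        s1 = _qcd([("rs1", 1, 100, "A", "G", 1.5)])
        s2 = _qcd([("rs1", 1, 100, "G", "A", 2.0)])
        pair = harmonize_pair(s1, s2)
        assert pair.table["z2"].iloc[0] == -2.0

    def test_identical_orientation_unchanged_and_mismatch_dropped(self):
        s1 = _qcd([("rs1", 1, 100, "A", "G", 1.5),
                   ("rs2", 1, 200, "A", "G", 0.5)])
        s2 = _qcd([("rs1", 1, 100, "A", "G", 2.0),
                   ("rs2", 1, 200, "C", "T", 0.9)])
        pair = harmonize_pair(s1, s2)
        assert pair.m == 1 and pair.table["z2"].iloc[0] == 2.0
        assert pair.counts["allele_mismatch"] == 1

    def test_complement_pair_is_treated_as_mismatch(self):
        # inputs are munged to one strand, so T/C against A/G is a data
        # error, not a strand flip
        s1 = _qcd([("rs1", 1, 100, "A", "G", 1.0),
                   ("rs2", 1, 200, "A", "G", 1.0)])
        s2 = _qcd([("rs1", 1, 100, "T", "C", 3.0),
                   ("rs2", 1, 200, "A", "G", 1.0)])
        pair = harmonize_pair(s1, s2)
        assert list(pair.table["snp"]) == ["rs2"]
        assert pair.counts["allele_mismatch"] == 1

    def test_empty_intersection_is_fatal(self):
        s1 = _qcd([("rs1", 1, 100, "A", "G", 1.0)])
        s2 = _qcd([("rs9", 1, 100, "A", "G", 1.0)])
        with pytest.raises(ValueError, match="shared"):
            harmonize_pair(s1, s2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["AG", "AC", "TG", "TC"]),
                              st.booleans(),
                              st.floats(-5, 5, allow_nan=False)),
                    min_size=1, max_size=8))
    def test_harmonization_is_involutive(self, spec):
        """Re-harmonizing an already harmonized pair changes nothing."""
        rows1, rows2 = [], []
        for i, (pair_alleles, swap, z) in enumerate(spec):
            a, b = pair_alleles
            rows1.append((f"rs{i}", 1, 100 + i, a, b, 1.0))
            rows2.append((f"rs{i}", 1, 100 + i, b if swap else a,
                          a if swap else b, z))
        first = harmonize_pair(_qcd(rows1), _qcd(rows2))
        s2_aligned = _qcd([(r.snp, r.chrom, r.pos, rows1[i][3], rows1[i][4],
                            r.z2) for i, r in enumerate(first.table.itertuples())])
        second = harmonize_pair(_qcd(rows1), s2_aligned)
        np.testing.assert_array_equal(first.table["z2"], second.table["z2"])


class TestPartition:
    def test_parse_chr_prefixed_block(self, tmp_path):
        p = tmp_path / "part.txt"
        p.write_text("chr start stop\nchr2 176998822 180334969\n")
        part = read_partition(p)
        row = part.blocks.iloc[0]
        assert (row["chrom"], row["start"], row["stop"]) == \
            (2, 176998822, 180334969)

    def test_unsorted_rows_returned_sorted(self, tmp_path):
        p = tmp_path / "part.txt"
        p.write_text("chr start stop\n1 500 900\n1 100 500\n")
        part = read_partition(p)
        assert list(part.blocks["start"]) == [100, 500]

    def test_degenerate_and_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="stop <= start"):
            validate_partition(pd.DataFrame(
                {"chrom": [1], "start": [900], "stop": [900]}))
        with pytest.raises(ValueError, match="overlap"):
            validate_partition(pd.DataFrame(
                {"chrom": [1, 1], "start": [100, 400], "stop": [500, 900]}))


class TestAssignToBlocks:
    @staticmethod
    def _pair(positions):
        tab = pd.DataFrame({"snp": [f"rs{i}" for i in range(len(positions))],
                            "chrom": 1, "pos": positions,
                            "z1": 0.0, "z2": 0.0})
        return sumstats.HarmonizedPair(table=tab, n1=10, n2=10)

    def test_half_open_convention_and_accounting(self):
        part = GenomePartition(blocks=pd.DataFrame(
            {"chrom": [1, 1], "start": [100, 500], "stop": [500, 900]}))
        pair = self._pair([100, 499, 500, 899, 900, 50])
        idx = assign_to_blocks(pair, part)
        assert list(idx[0]) == [0, 1]      # start included, stop excluded
        assert list(idx[1]) == [2, 3]      # stop of block 0 opens block 1
        assert pair.counts["outside_partition"] == 2
        all_assigned = np.concatenate(list(idx.values()))
        assert len(np.unique(all_assigned)) == len(all_assigned)
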