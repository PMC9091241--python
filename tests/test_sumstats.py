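"""Reading, writing and harmonizing summary-statistics tables."""

import math

import pytest

from mrkit.sumstats import (
    DROPPED_PALINDROMIC,
    DROPPED_UNMATCHED,
    SIGN_FLIPPED,
    STRAND_AND_SIGN_FLIPPED,
    STRAND_FLIPPED,
    UNCHANGED,
    SummaryStatsTable,
    harmonize,
    read_sumstats,
    write_sumstats,
)

from conftest import make_variant

HEADER = (
    "variant_id\tchromosome\tbase_pair_location\teffect_allele\tother_allele"
    "\teffect_allele_frequency\tbeta\tstandard_error\tp_value\tn"
)


def write_lines(path, rows):
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")


class TestReadSumstats:
    def test_valid_file_passes_through(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1e-9\t100000",
            "rs2\t1\t2000\tC\tT\t0.2\t-0.05\t0.008\t4e-8\t100000",
            "rs3\t2\t3000\tT\tG\t0.4\t0.02\t0.012\t6e-8\t100000",
        ])
        t = read_sumstats(f, "x", "continuous")
        assert len(t) == 3 and t.n_dropped == 0
        assert t.records[0].beta == pytest.approx(0.1)

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1e-9\t100000",
            "rs2\t1\t2000\tC\tT\t0.2\t-0.05\t0\t4e-8\t100000",      # se = 0
            "rs3\t2\t3000\tAT\tG\t0.4\t0.02\t0.012\t6e-8\t100000",  # indel
        ])
        t = read_sumstats(f, "x", "continuous")
        assert len(t) == 1 and t.n_dropped == 2

    def test_lowercase_alleles_uppercased(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["rs1\t1\t1000\ta\tg\t0.3\t0.1\t0.01\t1e-9\t100000"])
        t = read_sumstats(f, "x", "continuous")
        assert t.records[0].effect_allele == "A"
        assert t.records[0].other_allele == "G"

    def test_missing_column_is_hard_error(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_sumstats(f, "x", "continuous")

    def test_zero_valid_rows_is_hard_error(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["rs1\t1\t1000\tA\tG\t0.3\t0.1\t0\t1e-9\t100000"])
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(f, "x", "continuous")

    def test_comma_delimited_and_column_map(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text(
            "SNP,chr,bp,EA,OA,freq,b,serr,p,N\n"
            "rs1,1,1000,A,G,0.3,0.1,0.01,1e-9,100000\n"
        )
        t = read_sumstats(
            f, "x", "continuous",
            column_map={
                "variant_id": "SNP", "chrom": "chr", "pos": "bp",
                "effect_allele": "EA", "other_allele": "OA", "eaf": "freq",
                "beta": "b", "se": "serr", "pvalue": "p", "n": "N",
            },
        )
        assert len(t) == 1


class TestWriteSumstats:
    def test_round_trip_identity(self, tmp_path, small_table):
        f = tmp_path / "t.tsv"
        write_sumstats(small_table, f)
        t2 = read_sumstats(f, small_table.trait_name, small_table.trait_type)
        assert len(t2) == len(small_table)
        for a, b in zip(small_table.records, t2.records):
            assert a == b

    def test_missing_eaf_round_trips_as_na(self, tmp_path):
        t = SummaryStatsTable("x", "continuous", [make_variant(eaf=None)])
        f = tmp_path / "t.tsv"
        write_sumstats(t, f)
        assert "\tNA\t" in f.read_text()
        t2 = read_sumstats(f, "x", "continuous")
        assert t2.records[0].eaf is None

    def test_empty_table_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_sumstats(SummaryStatsTable("x", "continuous", []), tmp_path / "t.tsv")


def _pair(exp_kwargs, out_kwargs):
    exp = SummaryStatsTable("e", "continuous", [make_variant(**exp_kwargs)])
    out = SummaryStatsTable("o", "binary", [make_variant(**out_kwargs)])
    return exp, out


class TestHarmonize:
    def test_identical_orientation_unchanged(self):
        exp, out = _pair(dict(beta=0.10), dict(beta=0.05))
        h = harmonize(exp, out, ["rs1"])
        v = h.variants[0]
        assert v.action == UNCHANGED and v.beta_outcome == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="G", beta=0.10),
            dict(effect_allele="G", other_allele="A", beta=0.05, eaf=0.30),
        )
        h = harmonize(exp, out, ["rs1"])
        v = h.variants[0]
        assert v.action == SIGN_FLIPPED
        assert v.beta_outcome == pytest.approx(-0.05)

    def test_strand_complement_kept(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="G", beta=0.10),
            dict(effect_allele="T", other_allele="C", beta=0.05),
        )
        h = harmonize(exp, out, ["rs1"])
        assert h.variants[0].action == STRAND_FLIPPED
        assert h.variants[0].beta_outcome == pytest.approx(0.05)

    def test_strand_and_swap_flips_sign(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="G", beta=0.10),
            dict(effect_allele="C", other_allele="T", beta=0.05, eaf=0.7),
        )
        h = harmonize(exp, out, ["rs1"])
        assert h.variants[0].action == STRAND_AND_SIGN_FLIPPED
        assert h.variants[0].beta_outcome == pytest.approx(-0.05)

    def test_palindromic_at_half_frequency_dropped(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="T", eaf=0.50),
            dict(effect_allele="A", other_allele="T", eaf=0.30),
        )
        h = harmonize(exp, out, ["rs1"])
        assert h.n_snps == 0
        assert h.dropped[0].action == DROPPED_PALINDROMIC

    def test_palindromic_concordant_low_maf_kept(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="T", eaf=0.20),
            dict(effect_allele="A", other_allele="T", eaf=0.22, beta=0.05),
        )
        h = harmonize(exp, out, ["rs1"])
        assert h.variants[0].action == UNCHANGED

    def test_palindromic_discordant_frequency_dropped(self):
        exp, out = _pair(
            dict(effect_allele="G", other_allele="C", eaf=0.20),
            dict(effect_allele="G", other_allele="C", eaf=0.80),
        )
        h = harmonize(exp, out, ["rs1"])
        assert h.dropped[0].action == DROPPED_PALINDROMIC

    def test_palindromic_high_maf_dropped_at_limit(self):
        exp, out = _pair(
            dict(effect_allele="A", other_allele="T", eaf=0.45),
            dict(effect_allele="A", other_allele="T", eaf=0.44),
        )
        h = harmonize(exp, out, ["rs1"], palindromic_maf_limit=0.42)
        assert h.dropped[0].action == DROPPED_PALINDROMIC

    def test_absent_from_outcome_dropped_unmatched(self):
        exp = SummaryStatsTable("e", "continuous", [make_variant()])
        out = SummaryStatsTable("o", "binary", [make_variant("rs9")])
        h = harmonize(exp, out, ["rs1"])
        assert h.dropped[0].action == DROPPED_UNMATCHED

    def test_retained_plus_dropped_partition_input(self):
        exp = SummaryStatsTable("e", "continuous", [
            make_variant("rs1"),
            make_variant("rs2", effect_allele="A", other_allele="T", eaf=0.5),
            make_variant("rs3"),
        ])
        out = SummaryStatsTable("o", "binary", [
            make_variant("rs1", beta=0.02),
            make_variant("rs2", effect_allele="A", other_allele="T", eaf=0.5),
        ])
        h = harmonize(exp, out, ["rs1", "rs2", "rs3"])
        assert h.n_snps + len(h.dropped) == 3

    def test_idempotence_on_harmonized_pair(self):
        """A pair already sharing one convention needs no further action."""
        exp = SummaryStatsTable("e", "continuous", [
            make_variant("rs1"), make_variant("rs2", pos=2000),
        ])
        out = SummaryStatsTable("o", "binary", [
            make_variant("rs1", beta=0.03), make_variant("rs2", beta=-0.02, pos=2000),
        ])
        h = harmonize(exp, out, ["rs1", "rs2"])
        assert all(v.action == UNCHANGED for v in h.variants)

    def test_sign_consistency_under_joint_negation(self):
        """Negating every beta in both studies leaves Wald ratios unchanged."""
        exp, out = _pair(dict(beta=0.10), dict(beta=0.05))
        exp_n, out_n = _pair(dict(beta=-0.10), dict(beta=-0.05))
        h = harmonize(exp, out, ["rs1"])
        hn = harmonize(exp_n, out_n, ["rs1"])
        r = h.variants[0].beta_outcome / h.variants[0].beta_exposure
        rn = hn.variants[0].beta_outcome / hn.variants[0].beta_exposure
        assert r == pytest.approx(rn)

    def test_snp_missing_from_exposure_is_error(self):
        exp = SummaryStatsTable("e", "continuous", [make_variant()])
        out = SummaryStatsTable("o", "binary", [make_variant()])
        with pytest.raises(ValueError, match="rs99"):
            harmonize(exp, out, ["rs99"])
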