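"""Genotype I/O, QC filtering, allele frequencies, and polarization."""

import numpy as np
import pandas as pd
import pytest

from clinescan import (
    GenotypeMatrix,
    minor_allele_freq,
    polarize,
    qc_filter,
    read_genotypes,
    write_vcf,
)
from clinescan.geno_io import GenotypeError

from conftest import make_matrix

NA = np.nan


def write_test_vcf(path, records, samples=("sA", "sB", "sC")):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1H>\n##contig=<ID=2H>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for rec in records:
            fh.write("\t".join(rec) + "\n")


class TestReadGenotypes:
    def test_basic_parse_and_dosage_coding(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_test_vcf(
            vcf,
            [
                ("1H", "101", "snp1", "A", "G", ".", ".", ".", "GT", "0/0", "0/1", "1/1"),
                ("1H", "201", "snp2", "C", "T", ".", ".", ".", "GT", "1/1", "./.", "0/0"),
            ],
        )
        g = read_genotypes(vcf)
        assert g.samples == ["sA", "sB", "sC"]
        assert g.n_snps == 2
        # 1-based VCF POS converted to 0-based internal
        assert list(g.variants["pos"]) == [100, 200]
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
        assert g.dosage[1, 1] != g.dosage[1, 1]  # missing -> nan

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_test_vcf(
            vcf,
            [
                ("1H", "101", "ok", "A", "G", ".", ".", ".", "GT", "0/0", "0/1", "1/1"),
                ("1H", "201", "multi", "A", "T,G", ".", ".", ".", "GT", "0/0", "0/1", "1/1"),
                ("1H", "301", "indel", "AT", "A", ".", ".", ".", "GT", "0/0", "0/1", "1/1"),
            ],
        )
        g = read_genotypes(vcf)
        assert g.n_snps == 1
        assert g.meta["n_skipped"] == 2

    def test_unreadable_and_empty_inputs_fatal(self, tmp_path):
        with pytest.raises(GenotypeError):
            read_genotypes(tmp_path / "missing.vcf")
        vcf = tmp_path / "empty.vcf"
        write_test_vcf(vcf, [("1H", "201", "multi", "A", "T,G", ".", ".", ".",
                              "GT", "0/0", "0/1", "1/1")])
        with pytest.raises(GenotypeError):
            read_genotypes(vcf)

    def test_vcf_round_trip_preserves_dosage(self, tmp_path, island_panel):
        g, _, _ = island_panel
        out = tmp_path / "rt.vcf"
        write_vcf(g, out)
        g2 = read_genotypes(out)
        assert g2.samples == g.samples
        # written in coordinate order; realign by snp_id
        order = [list(g2.variants["snp_id"]).index(s) for s in g.variants["snp_id"]]
        np.testing.assert_array_equal(g.dosage, g2.dosage[:, order])


class TestQcFilter:
    def test_removes_monomorphic_and_high_missing(self):
        g = make_matrix(
            [
                [0, 0, 2, 0],
                [0, 1, NA, 0],
                [0, 2, NA, 2],
                [0, 1, 2, 2],
            ]
        )
        # col0 monomorphic; col2 has 50% missing (> 0.20)
        out, report = qc_filter(g, max_missing=0.20)
        assert list(out.variants["snp_id"]) == ["v1", "v3"]
        assert report.n_monomorphic == 1
        assert report.n_high_missing == 1
        assert report.n_kept == 2

    def test_missingness_boundary_is_strict(self):
        # exactly 20% missing is kept, just above removed
        g = make_matrix([[0], [1], [2], [1], [NA]])
        out, _ = qc_filter(g, max_missing=0.20)
        assert out.n_snps == 1

    def test_complete_ld_cull_keeps_lower_missingness(self):
        col = [0, 0, 1, 2, 2, 0, 1, 2, 0, 2]
        col_miss = list(col)
        col_miss[0] = NA
        g = make_matrix(np.column_stack([col, col_miss]))
        out, report = qc_filter(g, cull_complete_ld=True)
        assert list(out.variants["snp_id"]) == ["v0"]
        assert report.n_complete_ld == 1

    def test_complete_ld_tie_drops_later_position(self):
        col = [0, 0, 1, 2, 2, 0, 1, 2, 0, 2]
        g = make_matrix(np.column_stack([col, col]))
        out, _ = qc_filter(g, cull_complete_ld=True)
        assert list(out.variants["snp_id"]) == ["v0"]

    def test_cross_chromosome_duplicates_kept(self):
        col = [0, 0, 1, 2, 2, 0, 1, 2, 0, 2]
        g = make_matrix(np.column_stack([col, col]), chrom=["1H", "2H"])
        out, report = qc_filter(g, cull_complete_ld=True)
        assert out.n_snps == 2
        assert report.n_complete_ld == 0

    def test_idempotent(self, island_panel):
        g, _, _ = island_panel
        once, _ = qc_filter(g, cull_complete_ld=True)
        twice, report2 = qc_filter(once, cull_complete_ld=True)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert report2.n_monomorphic == 0
        assert report2.n_high_missing == 0
        assert report2.n_complete_ld == 0

    def test_all_removed_is_fatal(self):
        g = make_matrix([[0, 2], [0, 2], [0, 2]])
        with pytest.raises(GenotypeError):
            qc_filter(g)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([0, 0, 1, 2], 0.375),  # f_alt = 3/8
            ([2, 2, 2], 0.0),  # fixed alt
            ([0, 2, NA, 2], 1 / 3),  # f_alt = 4/6 -> MAF 1/3
        ],
    )
    def test_maf_hand_counts(self, dosages, expected):
        g = make_matrix(np.asarray(dosages)[:, None])
        assert minor_allele_freq(g, 0) == pytest.approx(expected)

    def test_maf_all_missing_undefined(self):
        g = make_matrix([[NA], [NA]])
        assert np.isnan(minor_allele_freq(g, 0))

    def test_maf_bounded_by_half(self, island_panel):
        g, _, _ = island_panel
        maf = minor_allele_freq(g)
        ok = ~np.isnan(maf)
        assert ((maf[ok] >= 0) & (maf[ok] <= 0.5)).all()


class TestPolarize:
    def make_panel(self):
        # f_alt: v0 = 0.13 impossible with 4 samples; use 1/4 etc.
        return make_matrix(
            [[0, 2, 0], [0, 2, 2], [0, 2, 2], [2, 2, 2]],
            ref=["A", "C", "G"], alt=["G", "T", "A"],
        )

    def test_outgroup_matches_ref_alt_or_neither(self):
        g = self.make_panel()
        res = polarize(g, {"v0": "A", "v1": "T", "v2": "C"})
        # v0: ancestral=ref -> derived = f_alt = 0.25
        assert res.loc[0, "derived_freq"] == pytest.approx(0.25)
        # v1: ancestral=alt -> derived = 1 - f_alt = 0
        assert res.loc[1, "ancestral_allele"] == "T"
        assert res.loc[1, "derived_freq"] == pytest.approx(0.0)
        # v2: outgroup base matches neither -> unknown
        assert res.loc[2, "ancestral_allele"] is None
        assert np.isnan(res.loc[2, "derived_freq"])

    def test_derived_plus_ancestral_freq_is_one(self, island_panel):
        from clinescan import alt_allele_freq
        from clinescan.simulate import simulate_outgroup

        g, _, truth = island_panel
        table = simulate_outgroup(g, truth, mismatch_rate=0.0, rng=1)
        res = polarize(g, table.set_index("snp_id")["base"])
        f_alt = alt_allele_freq(g)
        anc_is_ref = res["ancestral_allele"].values == g.variants["ref"].values
        ancestral_freq = np.where(anc_is_ref, 1 - f_alt, f_alt)
        ok = ~res["derived_freq"].isna()
        np.testing.assert_allclose(
            res["derived_freq"][ok] + ancestral_freq[ok], 1.0, atol=1e-12
        )
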