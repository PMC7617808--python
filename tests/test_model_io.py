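"""Data model and file I/O: VAF arithmetic, decomposition, PED, panels."""

from __future__ import annotations

import textwrap

import pytest

from lupustrio.io import (
    read_gmt,
    read_joint_vcf,
    read_panel,
    read_ped,
    read_trio_vcf,
    read_variants_tsv,
    write_annotation,
)
from lupustrio.model import (
    ExpressionMatrix,
    GenePanel,
    GenotypeCall,
    TrioPedigree,
    VariantRecord,
)

MULTIALLELIC_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##INFO=<ID=GENE,Number=A,Type=String,Description="g">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tD1\tM1
    chr1\t100\t.\tA\tG\t.\tPASS\tGENE=X1\tGT:AD:DP:GQ\t0/1:10,10:20:99\t0/0:20,0:20:99\t0/0:22,0:22:99
    chr1\t200\t.\tA\tG,T\t.\tPASS\tGENE=X2,X2\tGT:AD:DP:GQ\t1/2:2,9,8:19:80\t0/1:10,9,0:19:90\t0/2:11,0,9:20:95
    chr1\t300\t.\tC\tT\t.\tPASS\tGENE=X3\tGT:AD:DP:GQ\t./.:0,0:0:0\t0/0:30,0:30:99\t0/0:30,0:30:99
    """
)


@pytest.fixture()
def trio_vcf(tmp_path):
    p = tmp_path / "trio.vcf"
    p.write_text(MULTIALLELIC_VCF)
    return p


@pytest.fixture()
def trio_ped() -> TrioPedigree:
    return TrioPedigree("FAM1", "P1", "D1", "M1")


class TestGenotypeCall:
    def test_vaf_from_allele_depths(self):
        assert GenotypeCall("s", (0, 1), ad_ref=10, ad_alt=10, dp=20).vaf == 0.5

    def test_vaf_absent_when_no_reads(self):
        assert GenotypeCall("s", (0, 0), ad_ref=0, ad_alt=0, dp=0).vaf is None

    def test_allele_depth_exceeding_dp_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCall("s", (0, 1), ad_ref=10, ad_alt=10, dp=15)


class TestVariantRecord:
    def test_invalid_position_and_alt(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "A", "A")

    def test_af_bounds(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "A", "G", af_eas=1.5)


class TestTrioVcf:
    def test_biallelic_site_vaf(self, trio_vcf, trio_ped):
        recs = read_trio_vcf(trio_vcf, trio_ped)
        rec, calls = recs[0]
        assert rec.key == ("chr1", 100, "A", "G")
        assert calls["P1"].vaf == 0.5

    def test_multiallelic_decomposed_into_two_records(self, trio_vcf, trio_ped):
        recs = read_trio_vcf(trio_vcf, trio_ped)
        at200 = [(r, c) for r, c in recs if r.pos == 200]
        assert [r.alt for r, _ in at200] == ["G", "T"]
        assert all(r.pos == 200 for r, _ in at200)

    def test_decomposition_remaps_genotypes_and_ad(self, trio_vcf, trio_ped):
        recs = read_trio_vcf(trio_vcf, trio_ped)
        (rec_g, calls_g), (rec_t, calls_t) = [(r, c) for r, c in recs if r.pos == 200]
        # proband 1/2: carries each alt exactly once
        assert calls_g["P1"].gt == (0, 1) and calls_t["P1"].gt == (0, 1)
        assert calls_g["P1"].ad_alt == 9 and calls_t["P1"].ad_alt == 8
        # father 0/1 carries only G; mother 0/2 carries only T
        assert calls_g["D1"].carries_alt and not calls_t["D1"].carries_alt
        assert calls_t["M1"].carries_alt and not calls_g["M1"].carries_alt

    def test_decomposition_conserves_alt_supporting_samples(self, trio_vcf, trio_ped):
        # at the multi-allelic site, 4 (sample, alt) carrier pairs before == after
        recs = read_trio_vcf(trio_vcf, trio_ped)
        carriers = sum(
            c.carries_alt for r, calls in recs if r.pos == 200 for c in calls.values()
        )
        assert carriers == 4  # P1 carries both alts, D1 carries G, M1 carries T

    def test_missing_genotype_is_none(self, trio_vcf, trio_ped):
        recs = read_trio_vcf(trio_vcf, trio_ped)
        rec, calls = [rc for rc in recs if rc[0].pos == 300][0]
        assert calls["P1"].gt is None and calls["P1"].vaf is None

    def test_missing_sample_raises_with_name(self, trio_vcf):
        bad = TrioPedigree("FAM1", "P1", "D1", "NOT_THERE")
        with pytest.raises(KeyError, match="NOT_THERE"):
            read_trio_vcf(trio_vcf, bad)


class TestPed:
    def test_three_row_family_yields_one_trio(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text("F1 D1 0 0 1 1\nF1 M1 0 0 2 1\nF1 P1 D1 M1 2 2\n")
        trios = read_ped(p)
        assert len(trios) == 1
        assert trios[0].proband_id == "P1" and trios[0].affected

    def test_missing_parent_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "b.ped"
        p.write_text("F1 M1 0 0 2 1\nF1 P1 0 M1 2 2\n")
        with caplog.at_level("WARNING", logger="lupustrio"):
            trios = read_ped(p)
        assert trios == []
        assert any("lacks a genotyped parent" in r.message for r in caplog.records)

    def test_circular_parentage_rejected(self, tmp_path):
        p = tmp_path / "c.ped"
        p.write_text("F1 A B X 1 1\nF1 B A Y 1 1\nF1 X 0 0 2 1\nF1 Y 0 0 2 1\n")
        with pytest.raises(ValueError, match="circular"):
            read_ped(p)

    def test_generator_ped_yields_all_families(self, sim_cohort):
        trios = read_ped(sim_cohort.ped)
        assert len(trios) == 50
        assert len({t.family_id for t in trios}) == 50


class TestPanelsAndSets:
    def test_monogenic_panel_has_49_genes(self, sim_cohort):
        panel = read_panel(sim_cohort.panel_paths["monogenic"], "monogenic")
        assert len(panel) == 49

    def test_panel_sizes_match_study_design(self, sim_cohort):
        assert len(read_panel(sim_cohort.panel_paths["gwas"], "gwas")) == 213
        assert len(read_panel(sim_cohort.panel_paths["eqtl"], "eqtl")) == 64

    def test_duplicate_symbol_collapsed_with_warning(self, tmp_path, caplog):
        p = tmp_path / "p.tsv"
        p.write_text("TYK2\nBLK\ntyk2\n")
        with caplog.at_level("WARNING", logger="lupustrio"):
            panel = read_panel(p, "x")
        assert len(panel) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_panel_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("\n")
        with pytest.raises(ValueError):
            read_panel(p, "empty")

    def test_gmt_line_parsing(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("pathwayX\tdesc\tA\tB\n")
        assert read_gmt(p) == {"pathwayX": frozenset({"A", "B"})}


class TestRoundTrip:
    def test_variant_table_round_trip(self, tmp_path):
        variants = [
            VariantRecord("chr2", 10, "A", "G", gene="TYK2", af_eas=0.001,
                          cadd_phred=23.5, dbsnp="rs1"),
            VariantRecord("chr3", 20, "C", "T", gene="C4A"),
        ]
        p = tmp_path / "v.tsv"
        write_annotation(variants, p)
        assert read_variants_tsv(p) == variants


class TestExpressionMatrix:
    def test_duplicate_gene_rows_rejected(self):
        import pandas as pd

        df = pd.DataFrame([[1.0], [2.0]], index=["G1", "G1"], columns=["ABC"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values=df)

    def test_negative_values_rejected(self):
        import pandas as pd

        df = pd.DataFrame([[-1.0]], index=["G1"], columns=["ABC"])
        with pytest.raises(ValueError):
            ExpressionMatrix(values=df)
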