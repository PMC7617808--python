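"""Kinship estimation, inheritance classification, compound hets, outliers."""

from __future__ import annotations

import numpy as np
import pytest

from lupustrio.model import GenotypeCall, InheritanceCall, Origin, Sex, VariantRecord
from lupustrio.trio import (
    DEFAULT_THRESHOLDS,
    classify_inheritance,
    estimate_kinship,
    find_compound_hets,
    flag_outlier_probands,
)

VAR = VariantRecord("chr5", 1000, "A", "G", gene="TYK2")
VAR_X = VariantRecord("chrX", 1000, "A", "G", gene="CYBB")


def gc(sample, gt, ad_ref, ad_alt, dp=None, gq=99):
    dp = dp if dp is not None else ad_ref + ad_alt
    return GenotypeCall(sample, gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp, gq=gq)


def gene_drop_trio(rng, n_sites):
    """Monte-Carlo oracle: direct gene-dropping of one trio."""
    af = rng.uniform(0.05, 0.5, n_sites)
    father = (rng.random((n_sites, 2)) < af[:, None]).astype(int)
    mother = (rng.random((n_sites, 2)) < af[:, None]).astype(int)
    child = np.stack(
        [
            father[np.arange(n_sites), rng.integers(0, 2, n_sites)],
            mother[np.arange(n_sites), rng.integers(0, 2, n_sites)],
        ],
        axis=1,
    )
    unrelated = (rng.random((n_sites, 2)) < af[:, None]).astype(int)
    return father.sum(1), mother.sum(1), child.sum(1), unrelated.sum(1)


class TestKinship:
    def test_identical_vectors_give_half(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 2000)
        est = estimate_kinship(g, g.copy(), pair=("a", "a2"))
        assert est.kinship == 0.5
        assert est.ibs0_rate == 0.0

    def test_parent_offspring_near_quarter(self):
        f, m, c, u = gene_drop_trio(np.random.default_rng(42), 5000)
        for parent in (f, m):
            est = estimate_kinship(parent, c)
            assert 0.17 <= est.kinship <= 0.33
            assert est.ibs0_rate == 0.0  # parent-offspring share one allele everywhere

    def test_unrelated_near_zero(self):
        f, m, c, u = gene_drop_trio(np.random.default_rng(42), 5000)
        est = estimate_kinship(c, u)
        assert -0.1 <= est.kinship <= 0.1

    def test_too_few_sites_is_an_error(self):
        with pytest.raises(ValueError, match="informative sites"):
            estimate_kinship([1, 0, 2], [1, 0, 2])


class TestClassifyInheritance:
    def test_textbook_de_novo_germline(self):
        call = classify_inheritance(
            VAR,
            gc("p", (0, 1), 10, 10),
            gc("f", (0, 0), 20, 0),
            gc("m", (0, 0), 22, 0),
        )
        assert call.origin == Origin.DE_NOVO_GERMLINE and call.quality_pass

    def test_low_alt_read_support_fails_gate(self):
        call = classify_inheritance(
            VAR,
            gc("p", (0, 1), 17, 3),
            gc("f", (0, 0), 30, 0),
            gc("m", (0, 0), 30, 0),
        )
        assert call.origin == Origin.UNRESOLVED and not call.quality_pass

    def test_low_vaf_de_novo_is_mosaic_suspect(self):
        call = classify_inheritance(
            VAR,
            gc("p", (0, 1), 30, 6),  # VAF 0.167, within the 10-26% band
            gc("f", (0, 0), 30, 0),
            gc("m", (0, 0), 30, 0),
        )
        assert call.origin == Origin.DE_NOVO_MOSAIC_SUSPECT and call.quality_pass

    def test_paternal_inheritance(self):
        call = classify_inheritance(
            VAR, gc("p", (0, 1), 10, 10), gc("f", (0, 1), 10, 10), gc("m", (0, 0), 20, 0)
        )
        assert call.origin == Origin.PATERNAL

    def test_biparental_ambiguous(self):
        call = classify_inheritance(
            VAR, gc("p", (0, 1), 10, 10), gc("f", (0, 1), 10, 10), gc("m", (0, 1), 10, 10)
        )
        assert call.origin == Origin.BIPARENTAL_AMBIGUOUS

    def test_homozygous_recessive(self):
        call = classify_inheritance(
            VAR, gc("p", (1, 1), 0, 20), gc("f", (0, 1), 10, 10), gc("m", (0, 1), 10, 10)
        )
        assert call.origin == Origin.HOMOZYGOUS_RECESSIVE

    def test_missing_parent_never_de_novo(self):
        call = classify_inheritance(
            VAR, gc("p", (0, 1), 10, 10), gc("f", None, 0, 0), gc("m", (0, 0), 20, 0)
        )
        assert call.origin == Origin.UNRESOLVED and not call.quality_pass

    def test_parental_read_contamination_tolerated(self):
        # one stray alt read in a parent does not abandon the de novo call
        call = classify_inheritance(
            VAR, gc("p", (0, 1), 10, 10), gc("f", (0, 0), 19, 1), gc("m", (0, 0), 22, 0)
        )
        assert call.origin == Origin.DE_NOVO_GERMLINE

    def test_hemizygous_male_x_uses_mother_only(self):
        call = classify_inheritance(
            VAR_X,
            gc("p", (0, 1), 10, 10),
            gc("f", None, 0, 0),  # father genotype irrelevant on male X
            gc("m", (0, 0), 30, 0),
            proband_sex=Sex.MALE,
        )
        assert call.origin == Origin.DE_NOVO_GERMLINE

    def test_deterministic(self):
        args = (VAR, gc("p", (0, 1), 10, 10), gc("f", (0, 0), 20, 0), gc("m", (0, 0), 22, 0))
        assert classify_inheritance(*args) == classify_inheritance(*args)


class TestCompoundHets:
    @staticmethod
    def _mk(gene, pos, origin):
        var = VariantRecord("chr19", pos, "A", "G", gene=gene)
        return var, InheritanceCall(origin, True)

    @pytest.mark.parametrize(
        "origins,expected_pairs",
        [
            ([Origin.PATERNAL, Origin.MATERNAL], 1),
            ([Origin.PATERNAL, Origin.PATERNAL], 0),
            ([Origin.PATERNAL, Origin.PATERNAL, Origin.MATERNAL], 2),
            ([Origin.BIPARENTAL_AMBIGUOUS, Origin.MATERNAL], 0),
        ],
    )
    def test_pair_enumeration(self, origins, expected_pairs):
        classified = [self._mk("ACP5", 100 + i, o) for i, o in enumerate(origins)]
        pairs = find_compound_hets(classified)
        # enumeration oracle: every (paternal, maternal) combination
        n_pat = sum(1 for o in origins if o == Origin.PATERNAL)
        n_mat = sum(1 for o in origins if o == Origin.MATERNAL)
        assert len(pairs) == expected_pairs == n_pat * n_mat

    def test_pairs_confined_to_one_gene(self):
        classified = [
            self._mk("ACP5", 100, Origin.PATERNAL),
            self._mk("SAMHD1", 200, Origin.MATERNAL),
        ]
        assert find_compound_hets(classified) == []


class TestOutlierFlagging:
    def test_two_extreme_probands_flagged(self):
        counts = {f"p{i}": c for i, c in enumerate([1, 0, 2, 1, 1, 2, 0, 1, 3, 1, 34, 33])}
        rep = flag_outlier_probands(counts)
        assert rep.flagged == {"p10", "p11"}

    def test_all_equal_counts_flags_nothing(self):
        rep = flag_outlier_probands({f"p{i}": 2 for i in range(10)})
        assert rep.flagged == frozenset()

    def test_small_cohort_flags_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="lupustrio"):
            rep = flag_outlier_probands({"a": 1, "b": 50})
        assert rep.flagged == frozenset() and rep.threshold is None

    def test_low_vaf_fraction_reported(self):
        rep = flag_outlier_probands(
            {f"p{i}": 1 for i in range(6)},
            denovo_vafs={"p0": [0.1, 0.2, 0.5, 0.6]},
        )
        assert rep.low_vaf_fraction["p0"] == 0.5

    def test_implanted_outliers_recovered(self, default_report):
        flagged = default_report["de_novo"]["outliers_flagged"]
        assert flagged == ["F049_P", "F050_P"]
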