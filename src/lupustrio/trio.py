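"""Relatedness checks, Mendelian-consistency classification and de novo calling.

The de novo caller compares the proband's genotype against both parents at
each decomposed biallelic site. A Mendelian violation (alt in the proband,
both parents confidently homozygous reference) is called de novo only when
read-level quality gates pass; the observed variant allele fraction (VAF)
then splits germline de novo calls (VAF >= 0.30) from suspected post-zygotic
mosaic variants (0.10 <= VAF < 0.30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    GenotypeCall,
    InheritanceCall,
    KinshipEstimate,
    Origin,
    Sex,
    VariantRecord,
)

logger = logging.getLogger("lupustrio")


@dataclass(frozen=True)
class InheritanceThresholds:
    """Quality gates and VAF bands for inheritance classification.

    ``min_alt_reads`` implements the minor-allele-read-count filter (alt
    reads < 5 discarded) on the proband; ``max_parent_alt_reads`` tolerates
    stray sequencing error in parental reads without abandoning a de novo
    call.
    """

    min_dp: int = 10
    min_gq: int = 20
    min_alt_reads: int = 5
    max_parent_alt_reads: int = 1
    mosaic_vaf_low: float = 0.10
    germline_vaf: float = 0.30


DEFAULT_THRESHOLDS = InheritanceThresholds()

_X_NAMES = {"X", "CHRX"}


# ---------------------------------------------------------------------------
# Kinship

def estimate_kinship(
    genotypes_a: Sequence[int],
    genotypes_b: Sequence[int],
    pair: tuple[str, str] = ("A", "B"),
    min_sites: int = 200,
) -> KinshipEstimate:
    """KING-robust within-pair kinship from alt-allele dosage vectors.

    ``genotypes_*`` hold 0/1/2 alt-dosages over shared biallelic autosomal
    sites (negative = missing). The estimator is

        kinship = (N_AaAa - 2 * N_AAaa) / (N_Aa(a) + N_Aa(b))

    where ``N_AaAa`` counts doubly heterozygous sites, ``N_AAaa`` counts
    opposite-homozygote (IBS0) sites and ``N_Aa(i)`` counts heterozygous
    sites in sample *i*. It is robust to allele-frequency misspecification:
    parent-offspring pairs sit near 0.25 with an IBS0 rate near zero,
    unrelated pairs near 0, duplicates / monozygotic twins at 0.5.
    """
    a = np.asarray(genotypes_a, dtype=int)
    b = np.asarray(genotypes_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    informative = (a == 1) | (b == 1) | (a != b)
    n_inf = int(informative.sum())
    if n_inf < min_sites:
        raise ValueError(
            f"only {n_inf} informative sites for pair {pair}; "
            f"need >= {min_sites} — add more shared biallelic sites"
        )
    het_a = a == 1
    het_b = b == 1
    n_aa_het = int((het_a & het_b).sum())
    n_ibs0 = int(((a == 0) & (b == 2)).sum() + ((a == 2) & (b == 0)).sum())
    denom = int(het_a.sum() + het_b.sum())
    if denom == 0:
        raise ValueError(f"no heterozygous sites in either sample of pair {pair}")
    kin = (n_aa_het - 2 * n_ibs0) / denom
    return KinshipEstimate(
        pair=pair, kinship=kin, ibs0_rate=n_ibs0 / a.size, n_sites=int(a.size)
    )


def dosage_vector(calls: Sequence[GenotypeCall]) -> np.ndarray:
    """Alt-dosage vector (missing genotype -> -1) for kinship estimation."""
    return np.array(
        [c.n_alt_alleles if c.n_alt_alleles is not None else -1 for c in calls],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# Inheritance classification

def _passes_proband_gates(call: GenotypeCall, th: InheritanceThresholds) -> bool:
    return call.dp >= th.min_dp and call.gq >= th.min_gq and call.ad_alt >= th.min_alt_reads


def _parent_confident_homref(call: GenotypeCall, th: InheritanceThresholds) -> bool:
    return (
        call.is_hom_ref
        and call.dp >= th.min_dp
        and call.ad_alt <= th.max_parent_alt_reads
    )


def classify_inheritance(
    variant: VariantRecord,
    proband: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    thresholds: InheritanceThresholds = DEFAULT_THRESHOLDS,
    proband_sex: Sex = Sex.UNKNOWN,
) -> InheritanceCall:
    """Classify one proband variant by comparison with parental genotypes.

    Deterministic and order-independent; missing evidence degrades
    ``quality_pass`` or resolves to ``unresolved``, never to a de novo call.
    Hemizygous male X calls are compared against the mother only.
    """
    th = thresholds
    hemi_x = (
        variant.chrom.upper().lstrip("CHR") in {"X"} or variant.chrom.upper() in _X_NAMES
    ) and proband_sex == Sex.MALE

    if proband.gt is None:
        return InheritanceCall(Origin.UNRESOLVED, False, "proband genotype missing")
    if not proband.carries_alt:
        return InheritanceCall(Origin.UNRESOLVED, True, "proband carries no alt allele")
    if mother.gt is None or (not hemi_x and father.gt is None):
        return InheritanceCall(Origin.UNRESOLVED, False, "parental genotype missing")

    base_quality = proband.dp >= th.min_dp and proband.gq >= th.min_gq
    note_hemi = "hemizygous X, maternal comparison only; " if hemi_x else ""

    if hemi_x:
        if mother.carries_alt:
            return InheritanceCall(Origin.MATERNAL, base_quality, note_hemi + "alt in mother")
        if _parent_confident_homref(mother, th) and _passes_proband_gates(proband, th):
            return _de_novo_band(proband, th, note_hemi)
        return InheritanceCall(
            Origin.UNRESOLVED, False, note_hemi + "maternal evidence insufficient"
        )

    f_carries, m_carries = father.carries_alt, mother.carries_alt

    if proband.is_het:
        if f_carries and not m_carries:
            return InheritanceCall(Origin.PATERNAL, base_quality, "alt in father only")
        if m_carries and not f_carries:
            return InheritanceCall(Origin.MATERNAL, base_quality, "alt in mother only")
        if f_carries and m_carries:
            return InheritanceCall(
                Origin.BIPARENTAL_AMBIGUOUS, base_quality, "alt in both parents"
            )
        # Mendelian violation: neither parent genotyped as carrier
        parents_clean = _parent_confident_homref(father, th) and _parent_confident_homref(
            mother, th
        )
        if parents_clean and _passes_proband_gates(proband, th):
            return _de_novo_band(proband, th, "")
        return InheritanceCall(
            Origin.UNRESOLVED,
            False,
            "Mendelian violation pattern but quality gates failed "
            f"(proband dp={proband.dp} gq={proband.gq} ad_alt={proband.ad_alt}; "
            f"father ad_alt={father.ad_alt} dp={father.dp}; "
            f"mother ad_alt={mother.ad_alt} dp={mother.dp})",
        )

    # proband homozygous alt
    if f_carries and m_carries:
        return InheritanceCall(
            Origin.HOMOZYGOUS_RECESSIVE, base_quality, "alt from both parents"
        )
    if not f_carries and not m_carries:
        parents_clean = _parent_confident_homref(father, th) and _parent_confident_homref(
            mother, th
        )
        if parents_clean and _passes_proband_gates(proband, th):
            return _de_novo_band(proband, th, "hom-alt proband, both parents hom-ref; ")
    return InheritanceCall(
        Origin.UNRESOLVED, False, "hom-alt proband inconsistent with parental genotypes"
    )


def _de_novo_band(
    proband: GenotypeCall, th: InheritanceThresholds, note_prefix: str
) -> InheritanceCall:
    vaf = proband.vaf
    if vaf is None:
        return InheritanceCall(Origin.UNRESOLVED, False, note_prefix + "no covering reads")
    if vaf >= th.germline_vaf:
        return InheritanceCall(
            Origin.DE_NOVO_GERMLINE, True, note_prefix + f"VAF={vaf:.3f}"
        )
    if vaf >= th.mosaic_vaf_low:
        return InheritanceCall(
            Origin.DE_NOVO_MOSAIC_SUSPECT,
            True,
            note_prefix + f"low VAF={vaf:.3f} suggests post-zygotic origin",
        )
    return InheritanceCall(
        Origin.UNRESOLVED, False, note_prefix + f"VAF={vaf:.3f} below mosaic band"
    )


# ---------------------------------------------------------------------------
# Compound heterozygotes

def find_compound_hets(
    classified: Sequence[tuple[VariantRecord, InheritanceCall]],
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Trans-configured rare variant pairs within a gene for one proband.

    Pairs one paternally inherited with one maternally inherited variant in
    the same gene; biparental-ambiguous variants cannot be phased to a
    haplotype and are excluded from pairing.
    """
    by_gene: dict[str, dict[Origin, list[VariantRecord]]] = {}
    for var, call in classified:
        if var.gene is None:
            continue
        if call.origin in (Origin.PATERNAL, Origin.MATERNAL):
            by_gene.setdefault(var.gene, {}).setdefault(call.origin, []).append(var)
    pairs = []
    for gene in sorted(by_gene):
        pats = sorted(by_gene[gene].get(Origin.PATERNAL, []), key=lambda v: v.key)
        mats = sorted(by_gene[gene].get(Origin.MATERNAL, []), key=lambda v: v.key)
        for p in pats:
            for m in mats:
                pairs.append((p, m))
    return pairs


# ---------------------------------------------------------------------------
# Outlier probands

@dataclass(frozen=True)
class OutlierReport:
    flagged: frozenset[str]
    threshold: Optional[float]
    low_vaf_fraction: Mapping[str, float]


def flag_outlier_probands(
    denovo_counts: Mapping[str, int],
    denovo_vafs: Optional[Mapping[str, Sequence[float]]] = None,
    iqr_multiplier: float = 3.0,
    low_vaf_cut: float = 0.30,
    min_cohort: int = 5,
) -> OutlierReport:
    """Flag probands with an extreme number of de novo calls.

    Uses the Tukey-style rule count > Q3 + ``iqr_multiplier`` * IQR over the
    cohort (ties broken toward *not* flagging); flagged probands are
    candidate somatic-mosaicism cases. Also reports, per proband, the
    fraction of de novo calls with VAF below ``low_vaf_cut``.
    """
    low_vaf_fraction: dict[str, float] = {}
    if denovo_vafs:
        for pid, vafs in denovo_vafs.items():
            vafs = [v for v in vafs if v is not None]
            low_vaf_fraction[pid] = (
                sum(1 for v in vafs if v < low_vaf_cut) / len(vafs) if vafs else 0.0
            )
    if len(denovo_counts) < min_cohort:
        logger.warning(
            "cohort of %d probands too small for outlier flagging", len(denovo_counts)
        )
        return OutlierReport(frozenset(), None, low_vaf_fraction)
    counts = np.array(list(denovo_counts.values()), dtype=float)
    q1, q3 = np.percentile(counts, [25, 75])
    cut = q3 + iqr_multiplier * (q3 - q1)
    flagged = frozenset(pid for pid, c in denovo_counts.items() if c > cut)
    return OutlierReport(flagged, float(cut), low_vaf_fraction)
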