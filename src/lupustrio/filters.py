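"""The rare-variant filtering cascade.

Stage order (default): decompose (done at VCF read) -> consequence
inclusion -> dual-population MAF filter -> read-level QC -> panel tagging.
Each stage logs in/out counts so the attrition of the screen is auditable.

The frequency filter excludes variants with MAF strictly greater than the
threshold (default 0.005) in *either* the global or the East-Asian
reference panel; variants absent from a panel are novel and pass that
panel's check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Consequence,
    GenePanel,
    INCLUDED_CONSEQUENCES,
    PolyPhen,
    Sift,
    VariantRecord,
)

logger = logging.getLogger("lupustrio")

_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "stop_gained": Consequence.NONSENSE,
    "stop_lost": Consequence.NONSENSE,
    "frameshift": Consequence.FRAMESHIFT_INDEL,
    "frameshift_variant": Consequence.FRAMESHIFT_INDEL,
    "frameshift_indel": Consequence.FRAMESHIFT_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "splice_canonical": Consequence.SPLICE_CANONICAL,
    "splice_donor_variant": Consequence.SPLICE_CANONICAL,
    "splice_acceptor_variant": Consequence.SPLICE_CANONICAL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}


def classify_consequence(label: str) -> tuple[Consequence, bool]:
    """Map an annotation consequence string to the enum and inclusion flag.

    Included classes are missense, nonsense, coding indels and canonical
    splice-site variants; unknown labels map to ``other`` and are excluded
    with a warning.
    """
    key = label.strip().lower()
    cons = _CONSEQUENCE_ALIASES.get(key)
    if cons is None:
        logger.warning("unknown consequence label %r -> other (excluded)", label)
        cons = Consequence.OTHER
    return cons, cons in INCLUDED_CONSEQUENCES


def splice_consequence(site: str, offset: int) -> tuple[Consequence, bool]:
    """Classify an intronic position relative to a splice junction.

    Canonical sites are +1/+2 of the 5' donor and -1/-2 of the 3' acceptor;
    anything deeper into the intron is ``other`` and excluded.
    """
    if site == "donor" and offset in (1, 2):
        return Consequence.SPLICE_CANONICAL, True
    if site == "acceptor" and offset in (-1, -2):
        return Consequence.SPLICE_CANONICAL, True
    return Consequence.OTHER, False


def maf_filter(variant: VariantRecord, threshold: float = 0.005) -> bool:
    """True iff the variant is rare in both reference panels.

    A population frequency strictly greater than ``threshold`` in either
    the global or the EAS panel fails the variant; an absent frequency
    (novel variant) passes that panel's check. AF exactly at the threshold
    passes (strict-exceedance reading of the exclusion rule).
    """
    for af in (variant.af_global, variant.af_eas):
        if af is not None and af > threshold:
            return False
    return True


def damage_consensus(
    variant: VariantRecord,
    cadd_cutoff: float = 20.0,
    min_agree: int = 2,
    min_available: int = 2,
) -> str:
    """Consensus in-silico damage call over PolyPhen-2, SIFT and CADD.

    ``likely_damaging`` when at least ``min_agree`` of the *available*
    predictors vote damaging (PolyPhen probably/possibly damaging, SIFT
    deleterious, CADD phred >= ``cadd_cutoff``) and at least
    ``min_available`` predictors are present; fewer predictors ->
    ``indeterminate``.
    """
    votes = []
    if variant.polyphen != PolyPhen.ABSENT:
        votes.append(variant.polyphen in (PolyPhen.PROBABLY_DAMAGING, PolyPhen.POSSIBLY_DAMAGING))
    if variant.sift != Sift.ABSENT:
        votes.append(variant.sift == Sift.DELETERIOUS)
    if variant.cadd_phred is not None:
        votes.append(variant.cadd_phred >= cadd_cutoff)
    if len(votes) < min_available:
        return "indeterminate"
    return "likely_damaging" if sum(votes) >= min_agree else "not_damaging"


def variant_panel_tags(gene: Optional[str], panels: Mapping[str, GenePanel]) -> frozenset[str]:
    """Panel names containing ``gene`` (empty set = in no panel)."""
    if gene is None:
        return frozenset()
    return frozenset(name for name, panel in panels.items() if gene in panel)


def proband_panel_category(tag_sets: Sequence[frozenset[str]]) -> str:
    """monogenic-carrier / gwas-only / none from a proband's variant tags."""
    tags = set().union(*tag_sets) if tag_sets else set()
    if "monogenic" in tags:
        return "monogenic-carrier"
    if "gwas" in tags:
        return "gwas-only"
    return "none"


# ---------------------------------------------------------------------------
# Cascade over a cohort table

@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.005
    min_dp: int = 10
    min_gq: int = 20
    stage_order: tuple[str, ...] = ("consequence", "maf", "qc", "panel_tag")


def _stage_consequence(df: pd.DataFrame, cfg: FilterConfig, panels) -> pd.DataFrame:
    included = {c.value for c in INCLUDED_CONSEQUENCES}
    return df[df["consequence"].isin(included)]


def _stage_maf(df: pd.DataFrame, cfg: FilterConfig, panels) -> pd.DataFrame:
    ok_global = df["af_global"].isna() | (df["af_global"] <= cfg.maf_threshold)
    ok_eas = df["af_eas"].isna() | (df["af_eas"] <= cfg.maf_threshold)
    return df[ok_global & ok_eas]


def _stage_qc(df: pd.DataFrame, cfg: FilterConfig, panels) -> pd.DataFrame:
    return df[(df["dp"] >= cfg.min_dp) & (df["gq"] >= cfg.min_gq)]


def _stage_panel_tag(df: pd.DataFrame, cfg: FilterConfig, panels) -> pd.DataFrame:
    df = df.copy()
    for name, panel in (panels or {}).items():
        df[f"in_{name}"] = df["gene"].map(
            lambda g: isinstance(g, str) and g in panel
        ).astype(bool)
    return df


_STAGES = {
    "consequence": _stage_consequence,
    "maf": _stage_maf,
    "qc": _stage_qc,
    "panel_tag": _stage_panel_tag,
}


def run_filter_cascade(
    table: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    panels: Optional[Mapping[str, GenePanel]] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the filtering cascade to a (proband, variant) cohort table.

    ``table`` needs columns ``consequence``, ``af_global``, ``af_eas``,
    ``dp``, ``gq`` and ``gene``. Returns the surviving rows plus a
    per-stage attrition log ``[{stage, n_in, n_out}, ...]``. An empty
    surviving set is a warning, not an error.
    """
    df = table
    attrition = []
    for stage in config.stage_order:
        fn = _STAGES.get(stage)
        if fn is None:
            raise KeyError(f"unknown cascade stage {stage!r}")
        n_in = len(df)
        df = fn(df, config, panels)
        attrition.append({"stage": stage, "n_in": n_in, "n_out": len(df)})
    if df.empty:
        logger.warning("filter cascade produced an empty variant set")
    return df.reset_index(drop=True), attrition
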