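"""End-to-end orchestration: one reproducible cohort run with a JSON report.

Stages: pedigree + relatedness verification -> inheritance classification
for every proband alt-carrying variant -> rare-variant filter cascade ->
per-proband/per-panel burden summaries and case-control statistics ->
over-representation analysis and candidate-gene prioritization. Every
threshold is echoed into the report for provenance; the report is a pure
function of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .burden import (
    burden_chisq,
    denovo_rate_comparison,
    gene_carrier_comparison,
    per_proband_counts,
)
from .filters import FilterConfig, damage_consensus, run_filter_cascade
from .io import (
    annotate_variants,
    read_annotation,
    read_expression,
    read_gmt,
    read_joint_vcf,
    read_panels,
    read_ped,
)
from .model import DE_NOVO_ORIGINS, Origin, TrioPedigree
from .prioritize import (
    expression_criterion,
    intersect_candidates,
    ora,
    top_pathways,
)
from .trio import (
    DEFAULT_THRESHOLDS,
    InheritanceThresholds,
    classify_inheritance,
    dosage_vector,
    estimate_kinship,
    flag_outlier_probands,
)

logger = logging.getLogger("lupustrio")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """Paths and thresholds for one cohort run."""

    vcf: Path
    ped: Path
    annotation: Path
    panels: Mapping[str, Path]
    gmt: Optional[Path] = None
    expression: Optional[Path] = None
    background_genes: Optional[Path] = None
    controls_rare: Optional[Path] = None
    controls_denovo: Optional[Path] = None
    control_gene_carriers: Optional[Path] = None
    out_dir: Optional[Path] = None
    thresholds: InheritanceThresholds = DEFAULT_THRESHOLDS
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    kinship_range: tuple[float, float] = (0.17, 0.354)
    kinship_min_sites: int = 200
    ora_top_n: int = 20
    ora_min_neg_log10_p: float = 4.0
    expression_mode: str = "argmax"
    carrier_panel: str = "eqtl"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def summarize_variant_types(table: pd.DataFrame) -> dict[str, float]:
    """Fractions of qualifying variants by consequence class.

    Indel classes are pooled; fractions over distinct variants sum to 1.
    """
    if table.empty:
        raise ValueError("no qualifying variants to summarize")
    uniq = table.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    pooled = uniq["consequence"].replace(
        {"frameshift_indel": "indel", "inframe_indel": "indel"}
    )
    frac = pooled.value_counts(normalize=True)
    out = {k: float(frac.get(k, 0.0)) for k in ("missense", "nonsense", "indel", "splice_canonical")}
    return out


def _classify_cohort(variants_calls, trios, thresholds) -> pd.DataFrame:
    rows = []
    trio_by_id = {t.proband_id: t for t in trios}
    for var, calls in variants_calls:
        for t in trios:
            pro = calls.get(t.proband_id)
            if pro is None or not pro.carries_alt:
                continue
            fa, mo = calls.get(t.father_id), calls.get(t.mother_id)
            ic = classify_inheritance(
                var, pro, fa, mo, thresholds=thresholds, proband_sex=t.proband_sex
            )
            rows.append(
                {
                    "family": t.family_id, "proband": t.proband_id,
                    "chrom": var.chrom, "pos": var.pos, "ref": var.ref, "alt": var.alt,
                    "gene": var.gene, "consequence": var.consequence.value,
                    "af_global": var.af_global, "af_eas": var.af_eas,
                    "polyphen": var.polyphen.value, "sift": var.sift.value,
                    "cadd_phred": var.cadd_phred, "clinvar": var.clinvar.value,
                    "dbsnp": var.dbsnp,
                    "dp": pro.dp, "gq": pro.gq, "ad_ref": pro.ad_ref,
                    "ad_alt": pro.ad_alt, "vaf": pro.vaf,
                    "origin": ic.origin.value, "quality_pass": ic.quality_pass,
                    "notes": ic.notes,
                    "damage": damage_consensus(var),
                }
            )
    cols = [
        "family", "proband", "chrom", "pos", "ref", "alt", "gene", "consequence",
        "af_global", "af_eas", "polyphen", "sift", "cadd_phred", "clinvar", "dbsnp",
        "dp", "gq", "ad_ref", "ad_alt", "vaf", "origin", "quality_pass", "notes",
        "damage",
    ]
    return pd.DataFrame(rows, columns=cols)


def _verify_relatedness(variants_calls, trios, config) -> tuple[list[TrioPedigree], dict]:
    kept, excluded, estimates = [], [], {}
    lo, hi = config.kinship_range
    for t in trios:
        vecs = {}
        for sid in t.samples:
            vecs[sid] = dosage_vector([calls[sid] for _, calls in variants_calls])
        try:
            kin_pf = estimate_kinship(
                vecs[t.proband_id], vecs[t.father_id],
                pair=(t.proband_id, t.father_id), min_sites=config.kinship_min_sites,
            )
            kin_pm = estimate_kinship(
                vecs[t.proband_id], vecs[t.mother_id],
                pair=(t.proband_id, t.mother_id), min_sites=config.kinship_min_sites,
            )
        except ValueError as exc:
            raise StageError("relatedness", str(exc)) from exc
        estimates[t.family_id] = {
            "proband_father": kin_pf.kinship, "proband_mother": kin_pm.kinship,
            "ibs0_father": kin_pf.ibs0_rate, "ibs0_mother": kin_pm.ibs0_rate,
        }
        if lo <= kin_pf.kinship <= hi and lo <= kin_pm.kinship <= hi:
            kept.append(t)
        else:
            logger.warning(
                "family %s excluded: kinship out of range (pf=%.3f pm=%.3f)",
                t.family_id, kin_pf.kinship, kin_pm.kinship,
            )
            excluded.append(t.family_id)
    return kept, {"estimates": estimates, "excluded": excluded}


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and return (and optionally write) the report."""
    try:
        trios = read_ped(config.ped)
        panels = read_panels(config.panels)
        samples = [s for t in trios for s in t.samples]
        variants_calls = read_joint_vcf(config.vcf, samples=samples)
        annotation = read_annotation(config.annotation)
        variants = annotate_variants([v for v, _ in variants_calls], annotation)
        variants_calls = list(zip(variants, (c for _, c in variants_calls)))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input_validation", str(exc)) from exc

    trios_kept, kinship_report = _verify_relatedness(variants_calls, trios, config)

    calls_df = _classify_cohort(variants_calls, trios_kept, config.thresholds)
    rare_df, attrition = run_filter_cascade(calls_df, config.filter_config, panels)

    probands = [t.proband_id for t in trios_kept]
    counts, count_summary = per_proband_counts(rare_df, panels, probands)

    # de novo calls among qualifying rare variants
    dnv_origins = {o.value for o in DE_NOVO_ORIGINS}
    dnv_df = rare_df[rare_df["origin"].isin(dnv_origins) & rare_df["quality_pass"]]
    dnv_counts = {p: 0 for p in probands}
    dnv_vafs: dict[str, list] = {p: [] for p in probands}
    for row in dnv_df.itertuples(index=False):
        dnv_counts[row.proband] += 1
        dnv_vafs[row.proband].append(row.vaf)
    outliers = flag_outlier_probands(dnv_counts, dnv_vafs)

    # proband categories over SLE panels
    categories = {}
    for p in probands:
        sub = rare_df[rare_df["proband"] == p]
        if ("in_monogenic" in sub.columns) and sub["in_monogenic"].any():
            categories[p] = "monogenic-carrier"
        elif ("in_gwas" in sub.columns) and sub["in_gwas"].any():
            categories[p] = "gwas-only"
        else:
            categories[p] = "none"
    cat_counts = {
        "monogenic-carrier": sum(1 for v in categories.values() if v == "monogenic-carrier"),
        "gwas-only": sum(1 for v in categories.values() if v == "gwas-only"),
        "none": sum(1 for v in categories.values() if v == "none"),
        "no-de-novo": sum(1 for p in probands if dnv_counts[p] == 0),
    }

    # per-kindred listing (paternal / maternal / de novo gene columns)
    kindreds = {}
    for t in trios_kept:
        sub = rare_df[rare_df["proband"] == t.proband_id]
        kindreds[t.family_id] = {
            "paternal": sorted(set(sub[sub["origin"] == Origin.PATERNAL.value]["gene"].dropna())),
            "maternal": sorted(set(sub[sub["origin"] == Origin.MATERNAL.value]["gene"].dropna())),
            "de_novo": sorted(set(sub[sub["origin"].isin(dnv_origins)]["gene"].dropna())),
        }

    variant_types = (
        summarize_variant_types(rare_df) if not rare_df.empty else None
    )

    # --- burden statistics vs controls
    burden_report = {}
    if config.controls_rare is not None:
        try:
            ctrl = pd.read_csv(config.controls_rare, sep="\t")
            case_vec = counts["sle_combined"].tolist()
            res = burden_chisq(case_vec, ctrl["sle_combined"].tolist())
            burden_report["rare_variant_chisq"] = {
                "statistic": res.statistic, "p": res.p, "dof": res.dof,
                "low_expected_warning": res.low_expected_warning,
                "table": res.table.tolist(), "expected": res.expected.tolist(),
            }
        except Exception as exc:
            raise StageError("burden", str(exc)) from exc
    if config.controls_denovo is not None:
        ctrl_dnv = pd.read_csv(config.controls_denovo, sep="\t")
        burden_report["denovo_rate"] = denovo_rate_comparison(
            dnv_counts, ctrl_dnv["denovo"].tolist(), exclude=sorted(outliers.flagged)
        )
    if config.control_gene_carriers is not None and config.carrier_panel in panels:
        cg = pd.read_csv(config.control_gene_carriers, sep="\t")
        panel_genes = sorted(panels[config.carrier_panel].genes)
        col = f"in_{config.carrier_panel}"
        case_carr = {}
        if col in rare_df.columns:
            sub = rare_df[rare_df[col]]
            case_carr = sub.groupby("gene")["proband"].nunique().to_dict()
        n_controls = int(
            pd.read_csv(config.controls_rare, sep="\t").shape[0]
        ) if config.controls_rare is not None else int(cg["carriers"].max() or 1)
        carrier_df = gene_carrier_comparison(
            case_carr, len(probands),
            dict(zip(cg["gene"], cg["carriers"])), n_controls, panel_genes,
        )
        burden_report["gene_carriers"] = carrier_df
    else:
        carrier_df = None

    # --- enrichment and prioritization
    enrichment_report = None
    candidates_report = None
    if config.gmt is not None and config.background_genes is not None and not rare_df.empty:
        collection = read_gmt(config.gmt)
        background = [
            g.strip() for g in Path(config.background_genes).read_text().splitlines() if g.strip()
        ]
        non_outlier = rare_df[~rare_df["proband"].isin(outliers.flagged)]
        query = sorted(set(non_outlier["gene"].dropna()))
        results = ora(query, collection, background)
        top = top_pathways(results, config.ora_top_n, config.ora_min_neg_log10_p)
        enrichment_report = {
            "n_tested": len(results),
            "top_pathways": [
                {
                    "term": r.term_id, "p": r.p, "q": r.q, "k": r.query_hits,
                    "K": r.term_genes, "neg_log10_p": r.neg_log10_p,
                }
                for r in top
            ],
        }
        dnv_genes = sorted(
            set(non_outlier[non_outlier["origin"].isin(dnv_origins)]["gene"].dropna())
        )
        if dnv_genes and config.expression is not None:
            expr = read_expression(config.expression)
            expr_flags = expression_criterion(
                dnv_genes, expr, mode=config.expression_mode
            )
            top_sets = [collection[r.term_id] for r in top]
            pathway_genes = set().union(*top_sets) if top_sets else set()
            venn, cands = intersect_candidates(
                dnv_genes,
                pathway_genes,
                [g for g, ok in expr_flags.items() if ok],
                panels=panels,
                top_sets=top_sets,
            )
            candidates_report = {
                "venn": venn,
                "candidates": [
                    dataclasses.asdict(c) | {"is_candidate": c.is_candidate}
                    for c in cands
                ],
                "n_candidates": sum(1 for c in cands if c.is_candidate),
            }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_trios_input": len(trios),
        "n_trios_analyzed": len(trios_kept),
        "kinship": kinship_report,
        "attrition": attrition,
        "per_panel_totals": {
            name: {
                "variants": int(rare_df[f"in_{name}"].sum()) if f"in_{name}" in rare_df else 0,
                "genes": int(rare_df[rare_df[f"in_{name}"]]["gene"].nunique())
                if f"in_{name}" in rare_df else 0,
            }
            for name in panels
        },
        "count_summary": count_summary,
        "proband_categories": cat_counts,
        "de_novo": {
            "counts": dnv_counts,
            "total": int(sum(dnv_counts.values())),
            "median": float(np.median(list(dnv_counts.values()))) if dnv_counts else None,
            "outliers_flagged": sorted(outliers.flagged),
            "outlier_threshold": outliers.threshold,
            "low_vaf_fraction": dict(outliers.low_vaf_fraction),
        },
        "variant_type_fractions": variant_types,
        "burden": burden_report,
        "enrichment": enrichment_report,
        "prioritization": candidates_report,
        "kindreds": kindreds,
        "thresholds": {
            **dataclasses.asdict(config.thresholds),
            **dataclasses.asdict(config.filter_config),
            "kinship_range": list(config.kinship_range),
            "ora_top_n": config.ora_top_n,
            "ora_min_neg_log10_p": config.ora_min_neg_log10_p,
            "expression_mode": config.expression_mode,
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rare_df.to_csv(out / "rare_variants.tsv", sep="\t", index=False)
        calls_df.to_csv(out / "inheritance_calls.tsv", sep="\t", index=False)
        counts.to_csv(out / "burden_table.tsv", sep="\t")
        if carrier_df is not None:
            carrier_df.to_csv(out / "gene_carriers.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report_json(report))

    return report


def report_json(report: dict) -> str:
    """Canonical JSON serialization of the report (stable across runs)."""

    def _walk(x):
        if isinstance(x, dict):
            return {str(k): _walk(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_walk(v) for v in x]
        if isinstance(x, pd.DataFrame):
            return _walk(x.to_dict(orient="records"))
        if isinstance(x, np.ndarray):
            return _walk(x.tolist())
        if isinstance(x, (frozenset, set)):
            return sorted(str(v) for v in x)
        if isinstance(x, Path):
            return str(x)
        if isinstance(x, np.integer):
            return int(x)
        if isinstance(x, (float, np.floating)):
            f = float(x)
            if np.isnan(f):
                return None
            if np.isinf(f):
                return "inf" if f > 0 else "-inf"
            return f
        return x

    return json.dumps(_walk(report), indent=1, sort_keys=True)
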