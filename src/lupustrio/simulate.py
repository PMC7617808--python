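"""Synthetic trio-cohort generator.

Emulates the statistical structure of a 50-trio childhood-onset SLE
whole-exome study: per-proband rare-variant counts in SLE panels with a
median near 6 (Poisson, monogenic + GWAS components), Poisson de novo
counts with median 1, a low-VAF (10-26%) post-zygotic mosaic subpopulation
concentrated in two outlier probands, matched control cohorts without case
enrichment, and common background sites for relatedness checks.

Parental genotypes at background sites are drawn under Hardy-Weinberg from
a uniform allele-frequency spectrum; offspring genotypes are produced by
Mendelian gene dropping. Implanted variants (inherited and de novo) sit at
sites private to their family. Read depths follow a negative binomial;
alt read counts are binomial in the true VAF. One RNG stream per family,
keyed by (seed, family index), keeps cohorts extensible without perturbing
existing families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import resources
from .io import write_gmt, write_ped
from .model import Sex, TrioPedigree

_BASES = np.array(list("ACGT"))

# consequence mix of qualifying coding variants (dominantly missense)
DEFAULT_CONSEQUENCE_PROBS = {
    "missense": 0.92,
    "nonsense": 0.03,
    "frameshift_indel": 0.02,
    "inframe_indel": 0.01,
    "splice_canonical": 0.02,
}

_CLINVAR_CLASSES = ["VUS", "absent", "LB", "B", "CI", "P_LP"]
_CLINVAR_PROBS = [0.50, 0.40, 0.05, 0.03, 0.015, 0.005]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Rates are per proband. The default monogenic + GWAS rare-variant rates
    sum to 6.0 so the per-proband count of qualifying rare variants in SLE
    panels has median 6; the de novo Poisson mean of 1.2 yields median 1
    with a realistic upper tail. Outlier probands receive an extra
    Poisson(30) somatic-like component with VAF ~ U(0.10, 0.26). Control
    rates carry no case enrichment: 3.0 rare variants per individual and
    0.79 de novo variants per individual (1619 variants / 2049 controls).
    """

    seed: int
    n_trios: int = 50
    n_background_sites: int = 1200
    monogenic_rate: float = 1.3
    gwas_rate: float = 4.7
    de_novo_rate: float = 1.2
    mosaic_fraction: float = 0.08
    mosaic_vaf: tuple[float, float] = (0.10, 0.26)
    n_outlier_probands: int = 2
    outlier_somatic_rate: float = 30.0
    mean_dp: float = 40.0
    dp_dispersion: float = 8.0
    error_rate: float = 0.002
    noiseless: bool = False
    novel_af_fraction: float = 0.20
    damaging_fraction_panel: float = 0.42
    damaging_fraction_denovo: float = 0.216
    consequence_probs: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS))
    female_fraction: float = 0.784
    n_controls: int = 105
    control_rare_rate: float = 3.0
    n_denovo_controls: int = 2049
    control_denovo_rate: float = 0.79
    n_universe_genes: int = 3000

    def __post_init__(self) -> None:
        for name in (
            "monogenic_rate", "gwas_rate", "de_novo_rate", "outlier_somatic_rate",
            "control_rare_rate", "control_denovo_rate", "error_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.mosaic_fraction <= 1):
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        expected_implants = self.n_trios * (
            self.monogenic_rate + self.gwas_rate + self.de_novo_rate
        ) + self.n_outlier_probands * self.outlier_somatic_rate
        if expected_implants > 50_000:
            raise ValueError("implant rate infeasible for the site budget")


@dataclass
class SimulatedCohort:
    """File paths and ground truth of one simulated cohort."""

    out_dir: Path
    vcf: Path
    ped: Path
    annotation: Path
    panel_paths: dict[str, Path]
    gmt: Path
    expression: Path
    background_genes: Path
    controls_rare: Path
    controls_denovo: Path
    control_gene_carriers: Path
    truth_path: Path
    truth: pd.DataFrame
    trios: list[TrioPedigree]
    config: SimConfig


# ---------------------------------------------------------------------------
# gene geography

def _gene_map(config: SimConfig) -> tuple[dict[str, tuple[str, int]], list[str]]:
    """Assign each gene a (chrom, base position); 100 kb per gene slot."""
    mono = resources.monogenic_panel_genes()
    gwas = resources.gwas_panel_genes()
    dnv = [g for g in resources.denovo_gene_pool() if g not in set(mono) | set(gwas)]
    outl = [g for g in resources.outlier_gene_pool() if g not in set(mono) | set(gwas)]
    n_bg_genes = max(1, config.n_background_sites // 50)
    bg = [f"BGGN{i:04d}" for i in range(1, n_bg_genes + 1)]
    ordered = mono + gwas + dnv + outl + bg
    gmap = {}
    for i, gene in enumerate(ordered):
        chrom = f"chr{(i % 22) + 1}"
        base = 1_000_000 + (i // 22) * 100_000
        gmap[gene] = (chrom, base)
    return gmap, bg


def _draw_family_counts(rng: np.random.Generator, config: SimConfig) -> tuple[int, int, int]:
    """(monogenic, gwas, de novo) implant counts for one proband."""
    return (
        int(rng.poisson(config.monogenic_rate)),
        int(rng.poisson(config.gwas_rate)),
        int(rng.poisson(config.de_novo_rate)),
    )


def _panel_weights(genes: list[str]) -> np.ndarray:
    """Up-weight the well-known eQTL-validated genes so a handful of genes
    (TYK2, C4A, C4B, ...) dominate case carriers, as in real cohorts."""
    hot = set(resources.EQTL_KNOWN)
    return np.array([6.0 if g in hot else 1.0 for g in genes])


def _annotate_implant(
    rng: np.random.Generator, config: SimConfig, damaging_fraction: float
) -> dict:
    cons = rng.choice(
        list(config.consequence_probs), p=np.array(list(config.consequence_probs.values()))
        / sum(config.consequence_probs.values()),
    )
    novel = rng.random() < config.novel_af_fraction
    if novel:
        af_g = af_eas = None
        rsid = None
    else:
        af_eas = float(10 ** rng.uniform(-5, np.log10(0.004)))
        af_g = float(10 ** rng.uniform(-5, np.log10(0.004)))
        rsid = f"rs{rng.integers(10**6, 10**9)}"
    damaging = rng.random() < damaging_fraction
    if damaging:
        pph = "probably_damaging" if rng.random() < 0.7 else "possibly_damaging"
        sift = "deleterious"
        cadd = float(rng.uniform(20, 35))
    else:
        pph = "benign"
        sift = "tolerated"
        cadd = float(rng.uniform(0, 15))
    if rng.random() < 0.10:
        pph = "absent"
    if rng.random() < 0.10:
        sift = "absent"
    clinvar = rng.choice(_CLINVAR_CLASSES, p=_CLINVAR_PROBS)
    return {
        "consequence": str(cons), "af_global": af_g, "af_eas": af_eas,
        "polyphen": pph, "sift": sift, "cadd_phred": cadd,
        "clinvar": str(clinvar), "dbsnp": rsid,
    }


# ---------------------------------------------------------------------------
# main generator

def simulate_cohort(config: SimConfig, out_dir) -> SimulatedCohort:
    """Generate VCF + PED + annotation + panels + GMT + expression + truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gmap, bg_genes = _gene_map(config)
    mono_genes = resources.monogenic_panel_genes()
    gwas_genes = resources.gwas_panel_genes()
    eqtl_genes = set(resources.eqtl_panel_genes())
    dnv_pool = resources.denovo_gene_pool()
    outlier_pool = resources.outlier_gene_pool()

    rng_cohort = np.random.default_rng([config.seed, 10_001])

    # --- background sites (shared across the cohort)
    n_bg = config.n_background_sites
    bg_af = rng_cohort.uniform(0.05, 0.5, n_bg)
    bg_gene_idx = rng_cohort.integers(0, len(bg_genes), n_bg)
    bg_ref = rng_cohort.choice(4, n_bg)
    bg_alt = (bg_ref + rng_cohort.integers(1, 4, n_bg)) % 4
    bg_cons = rng_cohort.choice(
        ["synonymous", "missense", "other"], size=n_bg, p=[0.6, 0.3, 0.1]
    )
    per_gene_counter: dict[str, int] = {}
    bg_sites = []
    for i in range(n_bg):
        gene = bg_genes[bg_gene_idx[i]]
        off = per_gene_counter.get(gene, 0) + 1
        per_gene_counter[gene] = off
        chrom, base = gmap[gene]
        bg_sites.append(
            {
                "chrom": chrom, "pos": base + off, "ref": _BASES[bg_ref[i]],
                "alt": _BASES[bg_alt[i]], "gene": gene, "af": float(bg_af[i]),
                "consequence": str(bg_cons[i]),
            }
        )

    # --- per-family genotypes and implants
    trios: list[TrioPedigree] = []
    fam_background = {}  # family -> (father, mother, child) dosage arrays over bg sites
    implants = []  # rows: family, sample genotype trio implied by origin
    truth_rows = []
    outlier_families = set(range(config.n_trios - config.n_outlier_probands, config.n_trios))

    for fi in range(config.n_trios):
        rng = np.random.default_rng([config.seed, 20_000 + fi])
        fam = f"F{fi + 1:03d}"
        pid, fid, mid = f"{fam}_P", f"{fam}_F", f"{fam}_M"
        sex = Sex.FEMALE if rng.random() < config.female_fraction else Sex.MALE
        trios.append(TrioPedigree(fam, pid, fid, mid, proband_sex=sex, affected=True))

        # Hardy-Weinberg parents, gene-dropped child
        f_a = (rng.random((n_bg, 2)) < bg_af[:, None]).astype(int)
        m_a = (rng.random((n_bg, 2)) < bg_af[:, None]).astype(int)
        child = np.stack(
            [
                np.take_along_axis(f_a, rng.integers(0, 2, (n_bg, 1)), axis=1)[:, 0],
                np.take_along_axis(m_a, rng.integers(0, 2, (n_bg, 1)), axis=1)[:, 0],
            ],
            axis=1,
        )
        fam_background[fam] = (f_a.sum(axis=1), m_a.sum(axis=1), child.sum(axis=1))

        n_mono, n_gwas, n_dnv = _draw_family_counts(rng, config)
        chosen: list[tuple[str, str, float, str]] = []  # (gene, origin, vaf, class)
        for gene in rng.choice(
            mono_genes, size=n_mono, replace=True,
            p=_panel_weights(mono_genes) / _panel_weights(mono_genes).sum(),
        ):
            side = "paternal" if rng.random() < 0.5 else "maternal"
            chosen.append((str(gene), side, 0.5, "panel"))
        for gene in rng.choice(
            gwas_genes, size=n_gwas, replace=True,
            p=_panel_weights(gwas_genes) / _panel_weights(gwas_genes).sum(),
        ):
            side = "paternal" if rng.random() < 0.5 else "maternal"
            chosen.append((str(gene), side, 0.5, "panel"))
        dnv_genes = rng.choice(dnv_pool, size=min(n_dnv, len(dnv_pool)), replace=False)
        for gene in dnv_genes:
            if rng.random() < config.mosaic_fraction:
                vaf = float(rng.uniform(*config.mosaic_vaf))
                chosen.append((str(gene), "de_novo_mosaic", vaf, "denovo"))
            else:
                chosen.append((str(gene), "de_novo_germline", 0.5, "denovo"))
        if fi in outlier_families:
            n_som = int(rng.poisson(config.outlier_somatic_rate))
            som_genes = rng.choice(
                outlier_pool, size=min(n_som, len(outlier_pool)), replace=False
            )
            for gene in som_genes:
                vaf = float(rng.uniform(*config.mosaic_vaf))
                chosen.append((str(gene), "de_novo_mosaic", vaf, "denovo"))

        for gene, origin, vaf, klass in chosen:
            off = per_gene_counter.get(gene, 0) + 1
            per_gene_counter[gene] = off
            if off >= 99_000:
                raise ValueError(f"implant rate exceeds site budget for gene {gene}")
            chrom, base = gmap[gene]
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            ann = _annotate_implant(
                rng, config,
                config.damaging_fraction_panel if klass == "panel"
                else config.damaging_fraction_denovo,
            )
            implants.append(
                {
                    "family": fam, "chrom": chrom, "pos": base + off,
                    "ref": str(_BASES[ref_i]), "alt": str(_BASES[alt_i]),
                    "gene": gene, "origin": origin, "true_vaf": vaf, **ann,
                }
            )
            truth_rows.append(
                {
                    "family": fam, "proband": pid, "chrom": chrom, "pos": base + off,
                    "ref": str(_BASES[ref_i]), "alt": str(_BASES[alt_i]), "gene": gene,
                    "origin": origin, "true_vaf": vaf,
                    "in_monogenic": gene in set(mono_genes),
                    "in_gwas": gene in set(gwas_genes),
                    "in_eqtl": gene in eqtl_genes,
                    "is_outlier_somatic": fi in outlier_families and origin == "de_novo_mosaic"
                    and gene in set(outlier_pool),
                    "consequence": ann["consequence"],
                }
            )

    truth = pd.DataFrame(truth_rows)

    # --- assemble and write VCF
    samples = []
    for t in trios:
        samples.extend([t.father_id, t.mother_id, t.proband_id])
    vcf_path = out_dir / "cohort.vcf"
    ann_rows = []
    _write_vcf(
        vcf_path, samples, trios, bg_sites, fam_background, implants, config, ann_rows
    )

    annotation = pd.DataFrame(
        ann_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence", "af_global",
            "af_eas", "polyphen", "sift", "cadd_phred", "clinvar", "dbsnp",
        ],
    )
    ann_path = out_dir / "annotation.tsv"
    annotation.to_csv(ann_path, sep="\t", index=False)

    ped_path = out_dir / "cohort.ped"
    write_ped(trios, ped_path)

    # --- panels
    panel_dir = out_dir / "panels"
    panel_dir.mkdir(exist_ok=True)
    panel_paths = {}
    for name, genes in (
        ("monogenic", mono_genes), ("gwas", gwas_genes),
        ("eqtl", resources.eqtl_panel_genes()),
    ):
        p = panel_dir / f"{name}.tsv"
        p.write_text("\n".join(genes) + "\n")
        panel_paths[name] = p

    # --- gene universe, GMT, expression
    universe = _write_universe(out_dir, gmap, config)
    gmt_path = out_dir / "pathways.gmt"
    _write_pathways(gmt_path, universe, rng_cohort)
    expr_path = out_dir / "expression.tsv"
    _write_expression(expr_path, rng_cohort)

    # --- controls
    ctrl_rare, ctrl_dnv, ctrl_carriers = simulate_controls(config)
    cr_path = out_dir / "controls_rare.tsv"
    cd_path = out_dir / "controls_denovo.tsv"
    cg_path = out_dir / "control_gene_carriers.tsv"
    ctrl_rare.to_csv(cr_path, sep="\t", index=False)
    ctrl_dnv.to_csv(cd_path, sep="\t", index=False)
    ctrl_carriers.to_csv(cg_path, sep="\t", index=False)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(orient="records"), indent=1, default=str))

    return SimulatedCohort(
        out_dir=out_dir, vcf=vcf_path, ped=ped_path, annotation=ann_path,
        panel_paths=panel_paths, gmt=gmt_path, expression=expr_path,
        background_genes=out_dir / "background_genes.txt",
        controls_rare=cr_path, controls_denovo=cd_path,
        control_gene_carriers=cg_path, truth_path=truth_path, truth=truth,
        trios=trios, config=config,
    )


def _depth_calls(rng, config: SimConfig, vaf: float) -> tuple[int, int, int, int]:
    """(ad_ref, ad_alt, dp, gq) for one sample at one site."""
    if config.noiseless:
        dp = int(round(config.mean_dp))
        ad_alt = int(round(dp * vaf))
        return dp - ad_alt, ad_alt, dp, 99
    r = config.dp_dispersion
    p = r / (r + config.mean_dp)
    dp = max(1, int(rng.negative_binomial(r, p)))
    ad_alt = int(rng.binomial(dp, vaf))
    gq = min(99, 3 * dp)
    return dp - ad_alt, ad_alt, dp, gq


def _gt_string(dosage: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]


def _write_vcf(path, samples, trios, bg_sites, fam_background, implants, config, ann_rows):
    # one depth RNG stream per family, keyed by (seed, family index)
    depth_rngs = {
        t.family_id: np.random.default_rng([config.seed, 40_000 + fi])
        for fi, t in enumerate(trios)
    }
    sample_family = {}
    sample_role = {}
    for t in trios:
        for role, sid in (("F", t.father_id), ("M", t.mother_id), ("P", t.proband_id)):
            sample_family[sid] = t.family_id
            sample_role[sid] = role

    rows = []
    # background rows: every family genotyped
    for si, site in enumerate(bg_sites):
        entries = []
        for sid in samples:
            fam = sample_family[sid]
            f_d, m_d, c_d = fam_background[fam]
            dosage = {"F": f_d[si], "M": m_d[si], "P": c_d[si]}[sample_role[sid]]
            vaf = {0: config.error_rate if not config.noiseless else 0.0, 1: 0.5, 2: 1.0}[
                int(dosage)
            ]
            ar, aa, dp, gq = _depth_calls(depth_rngs[fam], config, vaf)
            entries.append(f"{_gt_string(int(dosage))}:{ar},{aa}:{dp}:{gq}")
        info = (
            f"GENE={site['gene']};CSQ={site['consequence']};"
            f"AF_G={site['af']:.6f};AF_EAS={site['af']:.6f}"
        )
        rows.append((site["chrom"], site["pos"], ".", site["ref"], site["alt"], info, entries))
        ann_rows.append(
            {
                "chrom": site["chrom"], "pos": site["pos"], "ref": site["ref"],
                "alt": site["alt"], "gene": site["gene"],
                "consequence": site["consequence"], "af_global": site["af"],
                "af_eas": site["af"], "polyphen": "absent", "sift": "absent",
                "cadd_phred": None, "clinvar": "absent", "dbsnp": None,
            }
        )

    # implant rows: carrier family only, everyone else hom-ref
    for imp in implants:
        fam = imp["family"]
        origin = imp["origin"]
        side_dosage = {"F": 0, "M": 0, "P": 1}
        if origin == "paternal":
            side_dosage["F"] = 1
        elif origin == "maternal":
            side_dosage["M"] = 1
        entries = []
        for sid in samples:
            if sample_family[sid] == fam:
                dosage = side_dosage[sample_role[sid]]
                vaf = imp["true_vaf"] if dosage == 1 and sample_role[sid] == "P" else (
                    0.5 if dosage == 1 else (config.error_rate if not config.noiseless else 0.0)
                )
            else:
                dosage = 0
                vaf = config.error_rate if not config.noiseless else 0.0
            ar, aa, dp, gq = _depth_calls(
                depth_rngs[sample_family[sid]], config, vaf
            )
            entries.append(f"{_gt_string(dosage)}:{ar},{aa}:{dp}:{gq}")
        info_parts = [f"GENE={imp['gene']}", f"CSQ={imp['consequence']}"]
        if imp["af_global"] is not None:
            info_parts.append(f"AF_G={imp['af_global']:.8f}")
            info_parts.append(f"AF_EAS={imp['af_eas']:.8f}")
        info_parts.append(f"PPH2={imp['polyphen']}")
        info_parts.append(f"SIFT={imp['sift']}")
        info_parts.append(f"CADD={imp['cadd_phred']:.2f}")
        info_parts.append(f"CLNSIG={imp['clinvar']}")
        if imp["dbsnp"]:
            info_parts.append(f"RS={imp['dbsnp']}")
        rows.append(
            (
                imp["chrom"], imp["pos"], imp["dbsnp"] or ".", imp["ref"], imp["alt"],
                ";".join(info_parts), entries,
            )
        )
        ann_rows.append(
            {
                "chrom": imp["chrom"], "pos": imp["pos"], "ref": imp["ref"],
                "alt": imp["alt"], "gene": imp["gene"],
                "consequence": imp["consequence"], "af_global": imp["af_global"],
                "af_eas": imp["af_eas"], "polyphen": imp["polyphen"],
                "sift": imp["sift"], "cadd_phred": imp["cadd_phred"],
                "clinvar": imp["clinvar"], "dbsnp": imp["dbsnp"],
            }
        )

    chrom_order = {f"chr{i}": i for i in range(1, 23)}
    rows.sort(key=lambda r: (chrom_order.get(r[0], 99), r[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lupustrio-simulator\n")
        for i in range(1, 23):
            fh.write(f"##contig=<ID=chr{i}>\n")
        for key, desc, num, typ in (
            ("GENE", "Gene symbol", "A", "String"),
            ("CSQ", "Consequence", "A", "String"),
            ("AF_G", "Global allele frequency", "A", "Float"),
            ("AF_EAS", "East-Asian allele frequency", "A", "Float"),
            ("PPH2", "PolyPhen-2 category", "A", "String"),
            ("SIFT", "SIFT category", "A", "String"),
            ("CADD", "CADD phred score", "A", "Float"),
            ("CLNSIG", "ClinVar class", "A", "String"),
            ("RS", "dbSNP id", "A", "String"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, info, entries in rows:
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:AD:DP:GQ\t"
                + "\t".join(entries) + "\n"
            )


# ---------------------------------------------------------------------------
# universe / pathways / expression

def _write_universe(out_dir: Path, gmap, config: SimConfig) -> list[str]:
    genes = list(gmap)
    filler = [f"UNIV{i:04d}" for i in range(1, max(0, config.n_universe_genes - len(genes)) + 1)]
    universe = genes + filler
    (out_dir / "background_genes.txt").write_text("\n".join(universe) + "\n")
    return universe


def _write_pathways(path, universe: list[str], rng: np.random.Generator) -> None:
    """20 SLE-like sets enriched for case genes plus 20 decoy sets.

    The designated top-pathway de novo genes are spread over the SLE sets
    with the configured cluster multiplicities (e.g. the most pleiotropic
    gene joins 7 of the 20 clusters).
    """
    top_genes = resources.top_pathway_denovo_genes()
    cluster_counts = dict(resources.CLUSTER_COUNTS)
    mono = resources.monogenic_panel_genes()
    gwas = resources.gwas_panel_genes()
    # keep the designated de novo genes out of the random panel draw so their
    # cluster multiplicities stay exactly as configured
    panel_pool = [g for g in mono + gwas if g not in set(top_genes)]
    non_query = [g for g in universe if g.startswith(("UNIV", "BGGN"))]

    sets: dict[str, list[str]] = {}
    n_sle = 20
    membership: dict[str, list[int]] = {}
    for gene in top_genes:
        k = cluster_counts.get(gene, int(rng.integers(1, 4)))
        membership[gene] = sorted(rng.choice(n_sle, size=k, replace=False).tolist())
    # weight panel members toward the frequently hit genes so every SLE set
    # overlaps the realized query strongly
    w = _panel_weights(panel_pool)
    w = w / w.sum()
    for i in range(n_sle):
        members = [g for g, sl in membership.items() if i in sl]
        members += list(rng.choice(panel_pool, size=18, replace=False, p=w))
        members += list(rng.choice(non_query, size=8, replace=False))
        sets[f"SLE_PATHWAY_{i + 1:02d}"] = sorted(set(members))
    for i in range(20):
        members = list(rng.choice(non_query, size=30, replace=False))
        sets[f"DECOY_PATHWAY_{i + 1:02d}"] = sorted(set(members))
    write_gmt(sets, path)


_CELL_TYPES = [
    "ABC", "plasma_cell", "naive_B", "memory_B", "GC_B", "T_cell", "NK_cell", "monocyte",
]


def _write_expression(path, rng: np.random.Generator) -> None:
    """Gene x cell-type matrix: 19 ABC-peaked and 12 plasma-peaked de novo
    genes, everything else peaking in a non-target cell type."""
    genes = (
        resources.denovo_gene_pool()
        + resources.outlier_gene_pool()
        + resources.monogenic_panel_genes()[:30]
        + resources.gwas_panel_genes()[:30]
    )
    genes = list(dict.fromkeys(genes))
    abc_high = set(resources.ABC_HIGH)
    plasma_high = set(resources.PLASMA_HIGH)
    rows = []
    for gene in genes:
        base = rng.uniform(0.5, 5.0, len(_CELL_TYPES))
        if gene in abc_high:
            base[0] = rng.uniform(8, 12)
        elif gene in plasma_high:
            base[1] = rng.uniform(8, 12)
        else:
            j = int(rng.integers(2, len(_CELL_TYPES)))
            base[j] = rng.uniform(8, 12)
        rows.append(base)
    df = pd.DataFrame(np.array(rows).round(3), index=genes, columns=_CELL_TYPES)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# controls

def simulate_controls(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Matched control count tables with no case enrichment.

    Returns per-individual rare-variant counts (monogenic/gwas/combined),
    per-individual de novo counts, and per-gene carrier counts over the
    eQTL panel (genes drawn uniformly, i.e. no hot genes).
    """
    rng = np.random.default_rng([config.seed, 50_000])
    case_total = config.monogenic_rate + config.gwas_rate
    share_mono = config.monogenic_rate / case_total if case_total > 0 else 0.5
    lam_mono = config.control_rare_rate * share_mono
    lam_gwas = config.control_rare_rate * (1 - share_mono)
    mono = rng.poisson(lam_mono, config.n_controls)
    gwas = rng.poisson(lam_gwas, config.n_controls)
    rare = pd.DataFrame(
        {
            "individual": [f"CTRL{i + 1:04d}" for i in range(config.n_controls)],
            "monogenic": mono,
            "gwas": gwas,
            "sle_combined": mono + gwas,
        }
    )
    dnv = pd.DataFrame(
        {
            "individual": [f"GDNV{i + 1:05d}" for i in range(config.n_denovo_controls)],
            "denovo": rng.poisson(config.control_denovo_rate, config.n_denovo_controls),
        }
    )
    eqtl = resources.eqtl_panel_genes()
    carriers = np.zeros(len(eqtl), dtype=int)
    for total in rare["sle_combined"]:
        if total == 0:
            continue
        hit = rng.choice(len(eqtl), size=int(total), replace=True)
        carriers[np.unique(hit)] += 1
    gene_carriers = pd.DataFrame({"gene": eqtl, "carriers": carriers})
    return rare, dnv, gene_carriers


def sample_count_replicates(config: SimConfig, n_probands: int, seed_offset: int = 60_000) -> pd.DataFrame:
    """Lightweight per-proband count draws (no VCF) for large replicates.

    Uses the same per-family count distributions as the full generator, so
    medians measured here reflect the cohort defaults.
    """
    rng = np.random.default_rng([config.seed, seed_offset])
    rows = []
    for _ in range(n_probands):
        n_mono, n_gwas, n_dnv = _draw_family_counts(rng, config)
        rows.append(
            {"monogenic": n_mono, "gwas": n_gwas, "sle_combined": n_mono + n_gwas,
             "denovo": n_dnv}
        )
    return pd.DataFrame(rows)
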