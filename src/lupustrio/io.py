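"""Readers and writers for VCF, PED, panel, GMT, annotation and expression files.

VCF parsing goes through :mod:`cyvcf2`. Multi-allelic sites are decomposed
on read: each alternate allele becomes its own :class:`VariantRecord`, and
genotype allele indices and AD columns are remapped so every record is
biallelic. Annotation is taken from the VCF INFO column when the generator's
keys are present, and can be overridden from a TSV annotation table.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    ClinVarClass,
    Consequence,
    ExpressionMatrix,
    GenePanel,
    GenotypeCall,
    PolyPhen,
    Sex,
    Sift,
    TrioPedigree,
    VariantRecord,
    normalize_symbol,
)

logger = logging.getLogger("lupustrio")

# INFO keys the synthetic generator writes (Number=A for per-alt fields)
_INFO_KEYS = ("GENE", "CSQ", "AF_G", "AF_EAS", "PPH2", "SIFT", "CADD", "CLNSIG", "RS")

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "af_global",
    "af_eas", "polyphen", "sift", "cadd_phred", "clinvar", "dbsnp",
]


# ---------------------------------------------------------------------------
# PED

def read_ped(path) -> list[TrioPedigree]:
    """Parse a 6-column PED file into complete trios.

    One trio is emitted per offspring whose father and mother ids both
    appear as individuals in the file; incomplete trios are logged and
    skipped. Circular parentage raises ``ValueError``.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: line {ln}: expected 6 PED columns")
            rows.append(parts[:6])

    individuals = {r[1] for r in rows}
    parent_of = {r[1]: (r[2], r[3]) for r in rows}

    # cycle detection on the parentage graph
    def _check_cycle(iid: str) -> None:
        seen = set()
        stack = [iid]
        while stack:
            cur = stack.pop()
            if cur in seen:
                raise ValueError(f"circular parentage involving {cur}")
            seen.add(cur)
            for p in parent_of.get(cur, ("0", "0")):
                if p != "0" and (p == iid or p in seen):
                    raise ValueError(f"circular parentage involving {iid}")
                if p != "0":
                    stack.append(p)

    trios: list[TrioPedigree] = []
    for fam, iid, pat, mat, sex, pheno in rows:
        if pat == "0" and mat == "0":
            continue  # founder
        _check_cycle(iid)
        if pat == "0" or mat == "0" or pat not in individuals or mat not in individuals:
            logger.warning("family %s: offspring %s lacks a genotyped parent; skipped", fam, iid)
            continue
        sex_e = {"1": Sex.MALE, "2": Sex.FEMALE}.get(sex, Sex.UNKNOWN)
        trios.append(
            TrioPedigree(
                family_id=fam,
                proband_id=iid,
                father_id=pat,
                mother_id=mat,
                proband_sex=sex_e,
                affected=(pheno == "2"),
            )
        )
    return trios


def write_ped(trios: Sequence[TrioPedigree], path, parent_sexes=True) -> None:
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t1\n")
            sex = {Sex.MALE: "1", Sex.FEMALE: "2"}.get(t.proband_sex, "0")
            pheno = "2" if t.affected else "1"
            fh.write(f"{t.family_id}\t{t.proband_id}\t{t.father_id}\t{t.mother_id}\t{sex}\t{pheno}\n")


# ---------------------------------------------------------------------------
# VCF

def _info_per_alt(value, alt_index: int, n_alts: int):
    """Pull the alt_index-th entry from a Number=A INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    if isinstance(value, str) and n_alts > 1 and "," in value:
        parts = value.split(",")
        return parts[alt_index] if alt_index < len(parts) else None
    return value


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def _enum_or(enum_cls, value, default):
    if value is None:
        return default
    try:
        return enum_cls(str(value))
    except ValueError:
        return default


def _record_from_site(v, alt_index: int) -> VariantRecord:
    n_alts = len(v.ALT)
    get = lambda key: _info_per_alt(v.INFO.get(key), alt_index, n_alts)
    dbsnp = get("RS")
    if dbsnp in (".", ""):
        dbsnp = None
    return VariantRecord(
        chrom=v.CHROM,
        pos=v.POS,
        ref=v.REF,
        alt=v.ALT[alt_index],
        gene=(normalize_symbol(str(get("GENE"))) if get("GENE") not in (None, ".") else None),
        consequence=_enum_or(Consequence, get("CSQ"), Consequence.OTHER),
        af_global=_parse_float(get("AF_G")),
        af_eas=_parse_float(get("AF_EAS")),
        polyphen=_enum_or(PolyPhen, get("PPH2"), PolyPhen.ABSENT),
        sift=_enum_or(Sift, get("SIFT"), Sift.ABSENT),
        cadd_phred=_parse_float(get("CADD")),
        clinvar=_enum_or(ClinVarClass, get("CLNSIG"), ClinVarClass.ABSENT),
        dbsnp=(str(dbsnp) if dbsnp is not None else None),
    )


def _calls_from_site(v, samples: Sequence[str], alt_index: int) -> dict[str, GenotypeCall]:
    ad = v.format("AD")
    dp_arr = v.gt_depths
    gq_arr = v.gt_quals
    allele_j = alt_index + 1
    calls: dict[str, GenotypeCall] = {}
    for si, sample in enumerate(samples):
        raw = v.genotypes[si]
        alleles = raw[:-1]  # last element is the phased flag
        hemizygous = len(alleles) == 1
        if hemizygous:
            alleles = [alleles[0], alleles[0]]
        if any(a < 0 for a in alleles):
            gt = None
        else:
            mapped = tuple(sorted(1 if a == allele_j else 0 for a in alleles))
            gt = mapped
        ad_ref = ad_alt = 0
        if ad is not None:
            row = ad[si]
            if len(row) > 0 and row[0] >= 0:
                ad_ref = int(row[0])
            if len(row) > allele_j and row[allele_j] >= 0:
                ad_alt = int(row[allele_j])
        dp = int(dp_arr[si]) if dp_arr is not None and dp_arr[si] >= 0 else 0
        dp = max(dp, ad_ref + ad_alt)
        gq = int(gq_arr[si]) if gq_arr is not None and gq_arr[si] >= 0 else 0
        calls[sample] = GenotypeCall(
            sample_id=sample, gt=gt, ad_ref=ad_ref, ad_alt=ad_alt,
            dp=dp, gq=gq, hemizygous=hemizygous,
        )
    return calls


def read_joint_vcf(path, samples: Optional[Sequence[str]] = None):
    """Read a (possibly multi-sample) VCF, decomposing multi-allelic sites.

    Returns a list of ``(VariantRecord, {sample_id: GenotypeCall})`` tuples.
    Requested samples missing from the header raise ``KeyError``.
    """
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise KeyError(f"sample id(s) not in VCF {path}: {', '.join(missing)}")
        vcf.set_samples(list(samples))
        use_samples = list(vcf.samples)
    else:
        use_samples = header_samples

    out = []
    row = 0
    try:
        for v in vcf:
            row += 1
            for alt_index in range(len(v.ALT)):
                rec = _record_from_site(v, alt_index)
                calls = _calls_from_site(v, use_samples, alt_index)
                out.append((rec, calls))
    except Exception as exc:  # cyvcf2 raises on malformed rows
        if isinstance(exc, (KeyError, ValueError)) and "line" in str(exc):
            raise
        raise ValueError(f"malformed VCF record near data line {row + 1} of {path}: {exc}") from exc
    finally:
        vcf.close()
    return out


def read_trio_vcf(path, pedigree: TrioPedigree):
    """Read one trio's variants: ``(VariantRecord, {sample: GenotypeCall})``."""
    return read_joint_vcf(path, samples=pedigree.samples)


# ---------------------------------------------------------------------------
# Panels / GMT / expression / annotation

def _read_symbol_column(path) -> list[str]:
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            # 1-column symbol file, or 2-column name/symbol file
            symbols.append(parts[-1])
    return symbols


def read_panel(path, name: str) -> GenePanel:
    symbols = [normalize_symbol(s) for s in _read_symbol_column(path)]
    if not symbols:
        raise ValueError(f"panel file {path} is empty")
    if len(symbols) != len(set(symbols)):
        dups = sorted({s for s in symbols if symbols.count(s) > 1})
        logger.warning("panel %s: duplicate symbols collapsed: %s", name, ", ".join(dups))
    return GenePanel.from_symbols(name, symbols)


def read_panels(paths: Mapping[str, object]) -> dict[str, GenePanel]:
    """Read panels from a ``{name: path}`` mapping."""
    return {name: read_panel(p, name) for name, p in paths.items()}


def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT gene-set collection: ``term<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: GMT needs term, description, >=1 gene")
            term = parts[0].strip()
            genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
            if term in sets:
                logger.warning("GMT %s: duplicate term %s overwritten", path, term)
            sets[term] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write(term + "\tna\t" + "\t".join(sorted(genes)) + "\n")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df)


def read_annotation(path) -> pd.DataFrame:
    """Variant annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "dbsnp": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks columns: {missing}")
    return df


def annotate_variants(
    variants: Sequence[VariantRecord], annotation: pd.DataFrame
) -> list[VariantRecord]:
    """Overlay TSV annotation onto variant records (TSV wins where present)."""
    idx = {}
    for row in annotation.itertuples(index=False):
        idx[(str(row.chrom), int(row.pos), row.ref, row.alt)] = row

    def _f(x):
        return None if pd.isna(x) else float(x)

    out = []
    for var in variants:
        row = idx.get(var.key)
        if row is None:
            out.append(var)
            continue
        out.append(
            dataclasses.replace(
                var,
                gene=(normalize_symbol(row.gene) if isinstance(row.gene, str) else var.gene),
                consequence=_enum_or(Consequence, row.consequence, var.consequence),
                af_global=_f(row.af_global),
                af_eas=_f(row.af_eas),
                polyphen=_enum_or(PolyPhen, row.polyphen, PolyPhen.ABSENT),
                sift=_enum_or(Sift, row.sift, Sift.ABSENT),
                cadd_phred=_f(row.cadd_phred),
                clinvar=_enum_or(ClinVarClass, row.clinvar, ClinVarClass.ABSENT),
                dbsnp=(row.dbsnp if isinstance(row.dbsnp, str) and row.dbsnp else None),
            )
        )
    return out


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "consequence": v.consequence.value,
                "af_global": v.af_global, "af_eas": v.af_eas,
                "polyphen": v.polyphen.value, "sift": v.sift.value,
                "cadd_phred": v.cadd_phred, "clinvar": v.clinvar.value,
                "dbsnp": v.dbsnp,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation(variants: Sequence[VariantRecord], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = read_annotation(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
                gene=(normalize_symbol(row.gene) if isinstance(row.gene, str) else None),
                consequence=_enum_or(Consequence, row.consequence, Consequence.OTHER),
                af_global=(None if pd.isna(row.af_global) else float(row.af_global)),
                af_eas=(None if pd.isna(row.af_eas) else float(row.af_eas)),
                polyphen=_enum_or(PolyPhen, row.polyphen, PolyPhen.ABSENT),
                sift=_enum_or(Sift, row.sift, Sift.ABSENT),
                cadd_phred=(None if pd.isna(row.cadd_phred) else float(row.cadd_phred)),
                clinvar=_enum_or(ClinVarClass, row.clinvar, ClinVarClass.ABSENT),
                dbsnp=(row.dbsnp if isinstance(row.dbsnp, str) and row.dbsnp else None),
            )
        )
    return out
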