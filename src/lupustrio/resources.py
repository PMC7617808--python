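"""Built-in gene lists for SLE-associated panels and the simulator.

The monogenic (49), GWAS (213) and eQTL-validated (64) panels carry the
well-known SLE genes by name (complement components, nucleic-acid
metabolism genes, interferon-pathway genes, B/T-cell tolerance genes) and
are padded to their published sizes with synthetic placeholder symbols so
that panel-size arithmetic downstream is realistic. Placeholder symbols are
clearly synthetic (``SLEG###`` / ``GWSG###``).
"""

from __future__ import annotations

MONOGENIC_KNOWN = [
    "ACP5", "C3", "C4A", "C4B", "DNASE1", "DNASE1L3", "IFIH1", "NRAS",
    "RNASEH2A", "RNASEH2B", "RNASEH2C", "SAMHD1", "ADA2", "TLR7", "TLR8",
    "UNC93B1", "SAT1", "TNIP1", "TMEM173", "TREX1", "FAS", "FASLG",
    "DOCK8", "LRBA", "CYBB", "MAN2B1", "SLC7A7", "DDX58", "NLRC4",
    "PACSIN1", "C1QA", "C1QB", "C1QC", "C1R", "C1S", "C2", "PRKCD",
    "PTEN", "KRAS", "STAT1", "STAT3", "JAK1", "DNASE2", "PEPD", "SHOC2",
    "RRAGD", "SOCS1", "ISG15", "SH2B3",
]  # 49

GWAS_KNOWN = [
    "TYK2", "BLK", "LYST", "UHRF1BP1", "IKBKE", "PHRF1", "P2RY8",
    "IRF5", "IRF7", "IRF8", "STAT4", "ITGAM", "TNFAIP3", "TNFSF4",
    "BANK1", "ETS1", "IKZF1", "IKZF2", "IKZF3", "PTPN22", "CSK",
    "RASGRP3", "NCF2", "WDFY4", "TNIP2", "ELF1", "AFF1", "PRDM1",
    "JAZF1", "UBE2L3", "SLC15A4", "CD44", "CD80", "CXCR5", "IL10",
    "IL12A", "IL12B", "FCGR2A", "FCGR2B", "FCGR3B", "CLEC16A",
]

EQTL_KNOWN = [
    "TYK2", "C4A", "C4B", "BLK", "LYST", "UHRF1BP1", "IKBKE", "IRF5",
    "IRF7", "STAT4", "ITGAM", "TNFAIP3", "BANK1", "ETS1", "IKZF1",
    "PTPN22", "UBE2L3", "SLC15A4", "FCGR2A", "CLEC16A", "NCF2", "ELF1",
]

# De novo gene pool mirroring the cohort structure: of 50 B-cell-expressed
# de novo genes, 19 peak in age-associated B cells (ABCs), 12 in plasma
# cells, 21 fall in top SLE pathways, and 12 satisfy both criteria.
ABC_HIGH = [
    "ACTR5", "AGO1", "ASAP1", "CTBP1", "DHX8", "FAM136A", "GFM2",
    "LRRC37B", "NRAS", "P2RY8", "PDE12", "PHRF1", "PLAGL1", "PNRC1",
    "PPARGC1B", "TET2", "TNRC6B", "WDR44", "ZNF232",
]  # 19

PLASMA_HIGH = [
    "ABLIM3", "ATRNL1", "DAND5", "GPRC5C", "LILRA6", "OR10D3", "PLEC",
    "RASAL1", "SLC35G5", "SLC51B", "TLX3", "WNT6",
]  # 12

# 12 genes in BOTH top pathways and ABC/plasma-high (subset of the 31 above)
PATHWAY_AND_EXPRESSION = [
    "NRAS", "P2RY8", "PDE12", "PPARGC1B", "DHX8", "ACTR5", "TET2",
    "PHRF1", "LILRA6", "RASAL1", "PLEC", "WNT6",
]  # 12

# 9 genes in top pathways but not ABC/plasma-high
PATHWAY_ONLY = [
    "GADD45A", "EREG", "DLC1", "MCM10", "ZEB2", "RBM17", "KDM5A",
    "SPTBN1", "ARHGEF2",
]  # 9

# 10 de novo genes in neither criterion
DNV_NEITHER = [
    "TTN", "OBSCN", "MUC16", "PCDH15", "CSMD1", "FAT4", "RYR2",
    "DNAH5", "USH2A", "LRP1B",
]  # 10

#: Gene -> number of top-pathway clusters it joins (most-clustered genes).
CLUSTER_COUNTS = {
    "PDE12": 7, "EREG": 5, "NRAS": 5, "PPARGC1B": 5,
    "GADD45A": 4, "LILRA6": 4,
}

OUTLIER_KNOWN = ["EPC1", "WASHC4", "STAB2"]


def _pad(known: list[str], prefix: str, size: int) -> list[str]:
    out = list(dict.fromkeys(known))
    i = 1
    while len(out) < size:
        sym = f"{prefix}{i:03d}"
        if sym not in out:
            out.append(sym)
        i += 1
    return out[:size]


def monogenic_panel_genes() -> list[str]:
    """49 genes implicated in monogenic SLE."""
    return _pad(MONOGENIC_KNOWN, "SLEG", 49)


def gwas_panel_genes() -> list[str]:
    """213 genes at SLE GWAS loci (disjoint from the monogenic panel)."""
    mono = set(monogenic_panel_genes())
    known = [g for g in GWAS_KNOWN if g not in mono]
    return _pad(known, "GWSG", 213)


def eqtl_panel_genes() -> list[str]:
    """64 eQTL-validated SLE genes, a subset of the monogenic+GWAS union."""
    union = monogenic_panel_genes() + gwas_panel_genes()
    known = [g for g in EQTL_KNOWN if g in union]
    padded = list(known)
    for g in union:
        if len(padded) >= 64:
            break
        if g not in padded:
            padded.append(g)
    return padded[:64]


def denovo_gene_pool() -> list[str]:
    """The 50-gene de novo pool (19 ABC-high, 12 plasma-high, 21 pathway)."""
    pool = ABC_HIGH + PLASMA_HIGH + PATHWAY_ONLY + DNV_NEITHER
    assert len(pool) == 50 and len(set(pool)) == 50
    return pool


def outlier_gene_pool() -> list[str]:
    """42 genes for the somatic-like variants of outlier probands."""
    return _pad(OUTLIER_KNOWN, "SOMG", 42)


def top_pathway_denovo_genes() -> list[str]:
    """The 21 de novo genes that cluster in top SLE pathways."""
    genes = PATHWAY_AND_EXPRESSION + PATHWAY_ONLY
    assert len(genes) == 21
    return genes


def expression_high_genes() -> list[str]:
    """The 31 de novo genes highly expressed in ABCs or plasma cells."""
    genes = ABC_HIGH + PLASMA_HIGH
    assert len(genes) == 31
    return genes
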