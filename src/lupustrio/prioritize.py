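"""Candidate-gene prioritization: over-representation analysis, B-cell
expression criterion, and their intersection.

Genes carrying qualifying rare variants are tested against a GMT gene-set
collection with the hypergeometric upper tail,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

where N is the background size, K the set size within the background, n
the query size and k the overlap. P-values are Benjamini-Hochberg adjusted
across tested sets. De novo genes that both fall in the top enriched
pathways and peak in age-associated B cells (ABCs) or plasma cells are the
prioritized candidates.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    CandidateGene,
    EnrichmentResult,
    ExpressionMatrix,
    GenePanel,
    normalize_symbol,
)

logger = logging.getLogger("lupustrio")


def ora(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    background: Iterable[str],
    min_set_size: int = 3,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene symbols are normalized; the query is clipped to the background;
    sets with fewer than ``min_set_size`` background genes are skipped.
    Results carry BH-adjusted q-values and are sorted by p (ties broken by
    term id).
    """
    bg = frozenset(normalize_symbol(g) for g in background)
    q = frozenset(normalize_symbol(g) for g in query) & bg
    if not q:
        raise ValueError("empty query after normalization/background restriction")
    N, n = len(bg), len(q)
    results = []
    for term, genes in collection.items():
        term_genes = frozenset(normalize_symbol(g) for g in genes) & bg
        K = len(term_genes)
        if K < min_set_size:
            continue
        overlap = q & term_genes
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term, term_genes=K, query_hits=k, query_size=n,
                background_size=N, p=min(p, 1.0), overlap_genes=overlap,
            )
        )
    if not results:
        return []
    results.sort(key=lambda r: (r.p, r.term_id))
    _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    return [
        EnrichmentResult(
            term_id=r.term_id, term_genes=r.term_genes, query_hits=r.query_hits,
            query_size=r.query_size, background_size=r.background_size,
            p=r.p, q=float(qv), overlap_genes=r.overlap_genes,
        )
        for r, qv in zip(results, qvals)
    ]


def top_pathways(
    results: Sequence[EnrichmentResult],
    top_n: int = 20,
    min_neg_log10_p: float = 4.0,
) -> list[EnrichmentResult]:
    """The ``top_n`` most significant sets with -log10(p) above threshold."""
    passing = [r for r in results if r.neg_log10_p > min_neg_log10_p]
    passing.sort(key=lambda r: (r.p, r.term_id))
    return passing[:top_n]


# ---------------------------------------------------------------------------
# Expression criterion

def _target_columns(expr: ExpressionMatrix, targets: Sequence[str]) -> list[str]:
    cols = []
    for ct in expr.cell_types:
        low = str(ct).lower()
        if any(t.lower() in low for t in targets):
            cols.append(ct)
    if not cols:
        raise ValueError(
            f"no expression column matches target cell types {list(targets)}; "
            f"columns are {expr.cell_types}"
        )
    return cols


def expression_criterion(
    genes: Iterable[str],
    expr: ExpressionMatrix,
    targets: Sequence[str] = ("ABC", "plasma"),
    mode: str = "argmax",
    z_cut: float = 1.5,
) -> dict[str, bool]:
    """Per-gene flag: highly expressed in ABCs or plasma cells.

    ``argmax`` mode (default): true iff the gene's expression in a target
    cell type strictly exceeds every non-target cell type. ``zscore`` mode:
    true iff the z-score across cell types in some target column is
    >= ``z_cut``. Genes absent from the matrix, and constant rows, are
    false.
    """
    df = expr.values
    target_cols = _target_columns(expr, targets)
    other_cols = [c for c in df.columns if c not in target_cols]
    out: dict[str, bool] = {}
    for gene in {normalize_symbol(g) for g in genes}:
        if gene not in df.index:
            logger.info("expression criterion: %s absent from matrix -> False", gene)
            out[gene] = False
            continue
        row = df.loc[gene]
        if float(row.max() - row.min()) == 0.0:
            out[gene] = False  # constant row: no argmax, z undefined
            continue
        if mode == "argmax":
            out[gene] = float(row[target_cols].max()) > float(row[other_cols].max())
        elif mode == "zscore":
            z = (row - row.mean()) / row.std(ddof=0)
            out[gene] = bool((z[target_cols] >= z_cut).any())
        else:
            raise ValueError(f"unknown expression mode {mode!r}")
    return out


def cluster_membership_count(
    gene: str, selected: Sequence[EnrichmentResult] | Sequence[frozenset[str]]
) -> int:
    """Number of selected pathway sets that contain ``gene``."""
    g = normalize_symbol(gene)
    n = 0
    for s in selected:
        members = s.overlap_genes if isinstance(s, EnrichmentResult) else s
        if g in {normalize_symbol(m) for m in members}:
            n += 1
    return n


def cluster_counts_from_sets(
    genes: Iterable[str], sets: Sequence[Iterable[str]]
) -> dict[str, int]:
    norm_sets = [frozenset(normalize_symbol(g) for g in s) for s in sets]
    return {
        normalize_symbol(g): sum(1 for s in norm_sets if normalize_symbol(g) in s)
        for g in genes
    }


# ---------------------------------------------------------------------------
# Intersection

def intersect_candidates(
    denovo_genes: Iterable[str],
    pathway_genes: Iterable[str],
    expression_positive: Iterable[str],
    panels: Optional[Mapping[str, GenePanel]] = None,
    top_sets: Optional[Sequence[Iterable[str]]] = None,
) -> tuple[dict[str, int], list[CandidateGene]]:
    """Venn of pathway vs expression support over the de novo genes.

    Returns ``(venn, candidates)`` where ``venn`` counts pathway-only,
    expression-only and both, and ``candidates`` lists every de novo gene
    with its flags, sorted by the number of supporting pathway clusters
    (then name); the prioritized candidates are those with both criteria.
    Input ordering is irrelevant.
    """
    dnv = frozenset(normalize_symbol(g) for g in denovo_genes)
    pw = frozenset(normalize_symbol(g) for g in pathway_genes) & dnv
    ex = frozenset(normalize_symbol(g) for g in expression_positive) & dnv
    venn = {
        "pathway_only": len(pw - ex),
        "expression_only": len(ex - pw),
        "both": len(pw & ex),
    }
    prior = frozenset()
    if panels:
        prior = frozenset().union(*(p.genes for p in panels.values()))
    clusters = (
        cluster_counts_from_sets(dnv, top_sets) if top_sets is not None else {}
    )
    cands = [
        CandidateGene(
            gene=g,
            in_top_pathways=g in pw,
            high_in_abc_or_plasma=g in ex,
            prior_sle_gene=g in prior,
            de_novo=True,
            n_pathway_clusters=clusters.get(g, 0),
        )
        for g in sorted(dnv)
    ]
    cands.sort(key=lambda c: (-c.n_pathway_clusters, c.gene))
    return venn, cands
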