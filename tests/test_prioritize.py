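"""ORA against enumeration, BH adjustment, expression criterion, Venn."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from lupustrio import resources
from lupustrio.io import read_expression
from lupustrio.model import ExpressionMatrix
from lupustrio.prioritize import (
    cluster_counts_from_sets,
    cluster_membership_count,
    expression_criterion,
    intersect_candidates,
    ora,
    top_pathways,
)


def enumeration_p(N: int, K: int, n: int, k: int) -> float:
    """Exhaustive oracle: fraction of n-draws with >= k hits in the K-set."""
    pop = range(N)
    in_set = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(pop, n):
        total += 1
        if len(in_set.intersection(draw)) >= k:
            hits += 1
    return hits / total


def run_ora(N, K, n):
    background = [f"G{i}" for i in range(N)]
    term = {"T": background[:K]}
    query = background[:n] if n <= K else background[:K] + background[K : n]
    # query drawn as the first n genes: overlap k = min(n, K)
    res = ora(query, term, background, min_set_size=1)[0]
    return res


class TestOraOracle:
    def test_small_case_one_sixth(self):
        # N=4, K=2, n=2, k=2: only 1 of C(4,2)=6 draws hits both set genes
        res = run_ora(4, 2, 2)
        assert res.p == pytest.approx(1 / 6, abs=1e-15)
        assert res.p == pytest.approx(enumeration_p(4, 2, 2, 2), abs=1e-15)

    def test_zero_overlap_gives_one(self):
        background = [f"G{i}" for i in range(6)]
        res = ora(background[3:], {"T": background[:3]}, background, min_set_size=1)[0]
        assert res.query_hits == 0 and res.p == 1.0

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 4), (12, 4, 7)])
    def test_matches_enumeration(self, N, K, n):
        res = run_ora(N, K, n)
        expected = enumeration_p(N, K, n, res.query_hits)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_small_sets_skipped_and_empty_query_rejected(self):
        background = [f"G{i}" for i in range(10)]
        assert ora(background[:3], {"tiny": background[:2]}, background) == []
        with pytest.raises(ValueError):
            ora(["NOT_IN_BG"], {"T": background[:5]}, background)


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        background = [f"G{i}" for i in range(40)]
        # three disjoint sets engineered to give ordered p-values
        coll = {
            "A": background[:12],
            "B": background[12:22],
            "C": background[22:30],
        }
        res = ora(background[:6] + background[12:16] + background[22:24],
                  coll, background, min_set_size=1)
        ps = [r.p for r in res]
        qs = [r.q for r in res]
        m = len(ps)
        # manual BH step-up: q_i = min_{j >= i} min(p_j * m / (j+1), 1)
        manual = [min(min(ps[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)]
        assert qs == pytest.approx(manual, abs=1e-12)
        # q monotone non-decreasing in rank order after step-up smoothing
        assert all(q2 >= q1 - 1e-15 for q1, q2 in zip(qs, qs[1:]))

    def test_three_element_vector(self):
        # p = [0.01, 0.02, 0.03] -> q = [0.03, 0.03, 0.03]
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert q.tolist() == pytest.approx([0.03, 0.03, 0.03], abs=1e-12)


class TestTopPathways:
    def test_threshold_and_count(self, sim_cohort, default_report):
        top = default_report["enrichment"]["top_pathways"]
        assert len(top) == 20
        assert all(t["neg_log10_p"] > 4.0 for t in top)
        assert all(t["term"].startswith("SLE_PATHWAY") for t in top)


def matrix(rows, genes, cols):
    return ExpressionMatrix(values=pd.DataFrame(rows, index=genes, columns=cols))


class TestExpressionCriterion:
    COLS = ["ABC", "plasma_cell", "T_cell", "NK_cell"]

    def test_strict_abc_maximum_is_true(self):
        m = matrix([[9.0, 1.0, 2.0, 3.0]], ["G1"], self.COLS)
        assert expression_criterion(["G1"], m)["G1"]

    def test_uniform_row_is_false(self):
        m = matrix([[2.0, 2.0, 2.0, 2.0]], ["G1"], self.COLS)
        assert not expression_criterion(["G1"], m)["G1"]

    def test_absent_gene_is_false(self):
        m = matrix([[9.0, 1.0, 2.0, 3.0]], ["G1"], self.COLS)
        assert not expression_criterion(["MISSING"], m)["MISSING"]

    def test_zscore_mode(self):
        m = matrix([[9.0, 1.0, 1.0, 1.0], [3.0, 2.9, 3.1, 2.95]], ["G1", "G2"], self.COLS)
        flags = expression_criterion(["G1", "G2"], m, mode="zscore")
        assert flags["G1"] and not flags["G2"]

    def test_generator_implants_exactly_19_abc_high(self, sim_cohort):
        expr = read_expression(sim_cohort.expression)
        pool = resources.denovo_gene_pool()
        abc_only = expression_criterion(pool, expr, targets=("ABC",))
        assert sum(abc_only.values()) == 19
        both = expression_criterion(pool, expr)
        assert sum(both.values()) == 31  # 19 ABC-high + 12 plasma-high


class TestClusterCounts:
    def test_fixture_counts(self):
        sets = [{"G", "X"} if i < 7 else {"X"} for i in range(20)]
        assert cluster_membership_count("G", sets) == 7
        assert cluster_membership_count("ABSENT", sets) == 0
        assert cluster_membership_count("X", sets) == 20

    def test_generator_cluster_multiplicities(self, sim_cohort):
        from lupustrio.io import read_gmt

        sets = [g for t, g in read_gmt(sim_cohort.gmt).items() if t.startswith("SLE")]
        counts = cluster_counts_from_sets(resources.CLUSTER_COUNTS, sets)
        assert counts == resources.CLUSTER_COUNTS


class TestIntersection:
    def test_set_algebra(self):
        venn, cands = intersect_candidates(
            ["A", "B", "C", "D"], ["A", "B", "C"], ["B", "C", "D"]
        )
        assert venn == {"pathway_only": 1, "expression_only": 1, "both": 2}
        both = {c.gene for c in cands if c.is_candidate}
        assert both == {"B", "C"}

    def test_study_structure_venn_9_19_12(self):
        """21 pathway genes and 31 expression genes sharing 12 of 50."""
        venn, cands = intersect_candidates(
            resources.denovo_gene_pool(),
            resources.top_pathway_denovo_genes(),
            resources.expression_high_genes(),
        )
        assert venn == {"pathway_only": 9, "expression_only": 19, "both": 12}
        assert sum(1 for c in cands if c.is_candidate) == 12

    def test_order_invariance(self):
        a = intersect_candidates(["A", "B", "C"], ["B", "A"], ["C", "B"])
        b = intersect_candidates(["C", "B", "A"], ["A", "B"], ["B", "C"])
        assert a == b

    def test_prior_sle_flag_from_panels(self):
        from lupustrio.model import GenePanel

        panels = {"gwas": GenePanel.from_symbols("gwas", ["NRAS"])}
        _, cands = intersect_candidates(["NRAS", "DHX8"], ["NRAS"], ["NRAS"], panels=panels)
        by_gene = {c.gene: c for c in cands}
        assert by_gene["NRAS"].prior_sle_gene and not by_gene["DHX8"].prior_sle_gene
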