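"""Case-control burden statistics for qualifying rare variants.

Per-individual counts of qualifying rare variants are compared between the
case cohort and controls by Pearson chi-square over binned counts (default
bins 0,1,2,3,4,>=5), per-gene carrier proportions are screened for >=2x
case enrichment, and de novo counts are compared by rate ratio plus a
two-sided Mann-Whitney test. A 2^-ddCt fold-change helper supports qPCR
follow-up of candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenePanel

logger = logging.getLogger("lupustrio")

DEFAULT_BINS = (0, 1, 2, 3, 4)  # last bin is open: >= bins[-1] + 1


def per_proband_counts(
    rare_table: pd.DataFrame,
    panels: Mapping[str, GenePanel],
    probands: Sequence[str],
    combined_name: str = "sle_combined",
    combine: tuple[str, ...] = ("monogenic", "gwas"),
) -> tuple[pd.DataFrame, dict]:
    """Distinct qualifying-variant counts per proband per panel.

    ``rare_table`` is the filtered cohort table with ``in_<panel>`` tag
    columns. Adds a combined column over the SLE panels. Medians use the
    midpoint-of-central-pair convention for even n (numpy default).
    """
    counts = pd.DataFrame(0, index=list(probands), columns=list(panels) + [combined_name])
    if not rare_table.empty:
        for name in panels:
            col = f"in_{name}"
            if col not in rare_table.columns:
                continue
            sub = rare_table[rare_table[col]]
            per = sub.groupby("proband")[["chrom", "pos", "ref", "alt"]].apply(
                lambda d: len(d.drop_duplicates())
            )
            counts.loc[per.index, name] = per
        combo_cols = [f"in_{n}" for n in combine if f"in_{n}" in rare_table.columns]
        if combo_cols:
            sub = rare_table[rare_table[combo_cols].any(axis=1)]
            per = sub.groupby("proband")[["chrom", "pos", "ref", "alt"]].apply(
                lambda d: len(d.drop_duplicates())
            )
            counts.loc[per.index, combined_name] = per
    summary = {
        col: {
            "median": float(np.median(counts[col])),
            "min": int(counts[col].min()),
            "max": int(counts[col].max()),
            "total": int(counts[col].sum()),
        }
        for col in counts.columns
    }
    return counts, summary


# ---------------------------------------------------------------------------
# Chi-square

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    dof: int
    table: np.ndarray
    expected: np.ndarray
    low_expected_warning: bool


def chisq_table(table) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    obs = np.asarray(table, dtype=float)
    # drop all-zero columns: they carry no information and break expected counts
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2:
        raise ValueError("degenerate contingency table: fewer than two informative bins")
    if obs.shape[0] == 2 and np.allclose(obs[0] / obs[0].sum(), obs[1] / obs[1].sum()):
        # identical row distributions: statistic exactly 0, p = 1
        expected = stats.contingency.expected_freq(obs)
        return ChiSquareResult(0.0, 1.0, obs.shape[1] - 1, obs, expected, bool((expected < 5).any()))
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    warn = bool((expected < 5).any())
    if warn:
        logger.debug("chi-square: expected cell count below 5; p-value approximate")
    return ChiSquareResult(float(stat), float(p), int(dof), obs, expected, warn)


def bin_counts(values: Sequence[int], bins: Sequence[int] = DEFAULT_BINS) -> np.ndarray:
    """Histogram of per-individual counts into 0,1,...,>=last+1 bins."""
    v = np.asarray(values, dtype=int)
    edges = list(bins)
    out = [int((v == b).sum()) for b in edges]
    out.append(int((v > edges[-1]).sum()))
    return np.array(out)


def burden_chisq(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    bins: Sequence[int] = DEFAULT_BINS,
    mode: str = "binned",
) -> ChiSquareResult:
    """Compare per-individual qualifying-variant counts between cohorts.

    ``mode='binned'`` builds a groups x bins contingency table over count
    bins; ``mode='carrier'`` collapses to a 2x2 carrier/non-carrier table.
    """
    if len(case_counts) == 0 or len(control_counts) == 0:
        raise ValueError("both cohorts must be non-empty")
    if mode == "carrier":
        cc = np.asarray(case_counts) > 0
        kk = np.asarray(control_counts) > 0
        table = [
            [int(cc.sum()), int((~cc).sum())],
            [int(kk.sum()), int((~kk).sum())],
        ]
        return chisq_table(table)
    table = np.vstack([bin_counts(case_counts, bins), bin_counts(control_counts, bins)])
    return chisq_table(table)


# ---------------------------------------------------------------------------
# Per-gene carrier comparison

def gene_carrier_comparison(
    case_carriers: Mapping[str, int],
    n_cases: int,
    control_carriers: Mapping[str, int],
    n_controls: int,
    genes: Sequence[str],
    min_ratio: float = 2.0,
) -> pd.DataFrame:
    """Per-gene carrier proportions and the >=2x case-enrichment list.

    A carrier is an individual with at least one qualifying rare variant in
    the gene. Control proportion 0 with case carriers yields an infinite
    ratio and is retained. Output sorted by case proportion (descending);
    ``enriched`` marks genes with ratio >= ``min_ratio``.
    """
    rows = []
    for gene in genes:
        case_p = case_carriers.get(gene, 0) / n_cases
        ctrl_p = control_carriers.get(gene, 0) / n_controls
        if ctrl_p > 0:
            ratio = case_p / ctrl_p
        else:
            ratio = np.inf if case_p > 0 else np.nan
        rows.append(
            {
                "gene": gene,
                "case_carriers": case_carriers.get(gene, 0),
                "case_proportion": case_p,
                "control_carriers": control_carriers.get(gene, 0),
                "control_proportion": ctrl_p,
                "ratio": ratio,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["case_proportion", "gene"], ascending=[False, True], ignore_index=True
    )
    df["enriched"] = (df["ratio"] >= min_ratio) & (df["case_carriers"] > 0)
    return df


# ---------------------------------------------------------------------------
# De novo rate comparison

def denovo_rate_comparison(
    case_counts: Mapping[str, int],
    control_counts: Sequence[int],
    exclude: Sequence[str] = (),
) -> dict:
    """Compare per-sample de novo counts between cases and controls.

    Reports mean counts and their ratio, a two-sided Mann-Whitney U test on
    the per-sample count vectors, and a sensitivity re-run excluding the
    flagged outlier probands.
    """
    case = np.array(list(case_counts.values()), dtype=float)
    ctrl = np.asarray(list(control_counts), dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both cohorts must be non-empty")

    def _one(case_vec):
        mean_case = float(case_vec.mean())
        mean_ctrl = float(ctrl.mean())
        ratio = mean_case / mean_ctrl if mean_ctrl > 0 else np.inf
        if np.array_equal(np.sort(case_vec), np.sort(ctrl)):
            p = 1.0
            u = float(case_vec.size * ctrl.size / 2)
        else:
            u, p = stats.mannwhitneyu(case_vec, ctrl, alternative="two-sided")
        return {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "rate_ratio": float(ratio),
            "mannwhitney_u": float(u),
            "p": float(p),
            "n_case": int(case_vec.size),
            "n_control": int(ctrl.size),
        }

    full = _one(case)
    kept = np.array(
        [c for pid, c in case_counts.items() if pid not in set(exclude)], dtype=float
    )
    sensitivity = _one(kept) if kept.size else None
    return {"all": full, "excluding_outliers": sensitivity, "excluded": sorted(exclude)}


# ---------------------------------------------------------------------------
# qPCR helper

def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    fold = 2 ** -((Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl))
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
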