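"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from lupustrio.io import annotate_variants, read_annotation, read_joint_vcf, read_ped
from lupustrio.pipeline import PipelineConfig, _classify_cohort, run_all
from lupustrio.simulate import SimConfig, simulate_cohort
from lupustrio.trio import DEFAULT_THRESHOLDS

COHORT_SEED = 11


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """Default 50-trio cohort with binomial read noise."""
    out = tmp_path_factory.mktemp("cohort_default")
    return simulate_cohort(SimConfig(seed=COHORT_SEED), out)


@pytest.fixture(scope="session")
def sim_noiseless(tmp_path_factory):
    """Default cohort in noiseless read mode (fixed depth, rounded AD)."""
    out = tmp_path_factory.mktemp("cohort_noiseless")
    return simulate_cohort(SimConfig(seed=COHORT_SEED, noiseless=True), out)


def pipeline_config(cohort, out_dir=None) -> PipelineConfig:
    return PipelineConfig(
        vcf=cohort.vcf,
        ped=cohort.ped,
        annotation=cohort.annotation,
        panels=cohort.panel_paths,
        gmt=cohort.gmt,
        expression=cohort.expression,
        background_genes=cohort.background_genes,
        controls_rare=cohort.controls_rare,
        controls_denovo=cohort.controls_denovo,
        control_gene_carriers=cohort.control_gene_carriers,
        out_dir=out_dir,
    )


@pytest.fixture(scope="session")
def default_report(sim_cohort):
    return run_all(pipeline_config(sim_cohort))


def classified_calls(cohort) -> pd.DataFrame:
    """Inheritance calls for every proband alt-carrying variant."""
    trios = read_ped(cohort.ped)
    vc = read_joint_vcf(cohort.vcf)
    variants = annotate_variants([v for v, _ in vc], read_annotation(cohort.annotation))
    vc = list(zip(variants, (c for _, c in vc)))
    return _classify_cohort(vc, trios, DEFAULT_THRESHOLDS)


@pytest.fixture(scope="session")
def noiseless_calls(sim_noiseless) -> pd.DataFrame:
    return classified_calls(sim_noiseless)


@pytest.fixture(scope="session")
def noiseless_truth_merge(sim_noiseless, noiseless_calls) -> pd.DataFrame:
    """Truth table joined with the caller's origin assignments."""
    return sim_noiseless.truth.merge(
        noiseless_calls,
        on=["proband", "chrom", "pos", "ref", "alt"],
        how="left",
        suffixes=("_true", ""),
    )
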