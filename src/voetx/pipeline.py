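"""End-to-end drivers composing the pipeline stages.

These helpers wire the stages together in the canonical order —
filter -> TMM -> log-CPM -> axis scores -> covariate adjustment -> paired
DGE -> enrichment -> biomarkers — and are what the analysis scripts and the
acceptance checks call. Each stage remains independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .adjust import AdjustedExpression, AxisScore, axis_score, supervised_adjust
from .biomarker import (
    BiomarkerPanel,
    PanelScore,
    group_difference_test,
    patient_fold_changes,
    pc1_scores,
    select_biomarkers,
)
from .compare import DownsampleResult, compare_strata
from .core import (
    CountMatrix,
    ExpressionMatrix,
    SampleMetadata,
    TimePoint,
    exclude_followup,
)
from .dge import DGEResult, run_dge
from .enrichment import EnrichmentResult, gsea, rank_statistic
from .preprocess import NormalizationFactors, filter_low_expression, log_cpm, tmm_factors
from .simulate import SimulationDesign, SyntheticTruth, comparison_design, simulate_cohort


@dataclass
class PreprocessResult:
    filtered: CountMatrix
    factors: NormalizationFactors
    logcpm: ExpressionMatrix
    axis_scores: list[AxisScore]
    adjusted: AdjustedExpression


@dataclass
class PipelineResult:
    counts: CountMatrix
    meta: list[SampleMetadata]
    truth: SyntheticTruth | None
    pre: PreprocessResult
    dge: DGEResult
    enrichment: EnrichmentResult
    panel: BiomarkerPanel | None
    panel_score: PanelScore | None
    panel_t: float | None
    panel_p: float | None


def preprocess_cohort(
    cm: CountMatrix,
    meta: Sequence[SampleMetadata],
    tcell_markers: Sequence[str],
    bcell_markers: Sequence[str],
    zero_fraction: float = 0.10,
    prior_count: float = 0.5,
) -> PreprocessResult:
    """Filter, normalize, log-transform and covariate-adjust one cohort."""
    filtered = filter_low_expression(cm, zero_fraction)
    factors = tmm_factors(filtered)
    logcpm = log_cpm(filtered, factors, prior_count)
    axes = [
        axis_score(logcpm, [g for g in tcell_markers if g in logcpm.gene_ids], "Tcell"),
        axis_score(logcpm, [g for g in bcell_markers if g in logcpm.gene_ids], "Bcell"),
    ]
    adjusted = supervised_adjust(logcpm, meta, axes)
    return PreprocessResult(filtered, factors, logcpm, axes, adjusted)


def run_cohort_analysis(
    design: SimulationDesign,
    n_perm: int = 1000,
    gsea_seed: int = 0,
    alpha: float = 0.05,
) -> PipelineResult:
    """Simulate one cohort and run the full analysis chain on it."""
    cm, meta, truth = simulate_cohort(design)
    pre = preprocess_cohort(cm, meta, truth.tcell_markers, truth.bcell_markers)
    dge = run_dge(pre.adjusted, meta)
    rl = rank_statistic(dge)
    enr = gsea(rl, truth.gene_sets, n_perm=n_perm, seed=gsea_seed)
    panel = panel_score = None
    panel_t = panel_p = None
    pfc, _ = patient_fold_changes(pre.adjusted.expression, meta)
    panel = select_biomarkers(pfc, dge, enr, truth.gene_sets, alpha=alpha)
    if len(panel.gene_ids) >= 2:
        panel_score = pc1_scores(pre.adjusted.expression, panel.gene_ids)
        active = exclude_followup(meta)
        keep = [s.sample_id for s in active]
        idx = [panel_score.sample_ids.index(s) for s in keep]
        groups = [
            "voe" if m.time_point is TimePoint.VOE else "steady_state" for m in active
        ]
        panel_t, panel_p = group_difference_test(panel_score.scores[idx], groups)
    return PipelineResult(
        counts=cm,
        meta=meta,
        truth=truth,
        pre=pre,
        dge=dge,
        enrichment=enr,
        panel=panel,
        panel_score=panel_score,
        panel_t=panel_t,
        panel_p=panel_p,
    )


def run_stratum_comparison(
    seed: int,
    chronic_multiplier: float = 1.5,
    b: int = 20,
    n_perm: int = 300,
) -> DownsampleResult:
    """Simulate a comparison cohort and run the bootstrap stratum comparison."""
    design = comparison_design(seed, chronic_multiplier=chronic_multiplier)
    cm, meta, truth = simulate_cohort(design)
    pre = preprocess_cohort(cm, meta, truth.tcell_markers, truth.bcell_markers)
    return compare_strata(
        pre.adjusted.expression,
        meta,
        truth.gene_sets,
        target="chronic_pain",
        b=b,
        n_perm=n_perm,
        seed=seed * 97 + 11,
        residual_df_loss=pre.adjusted.n_nuisance_dims,
    )


def null_dge_design(seed: int, n_genes: int = 5000, n_subjects: int = 20) -> SimulationDesign:
    """A nuisance-free fully-paired null cohort (no planted effects at all)."""
    return SimulationDesign(
        n_genes=n_genes,
        n_subjects=n_subjects,
        paired_fraction=1.0,
        planted_de_genes=0,
        planted_enriched_sets=(),
        n_null_sets=0,
        n_biomarkers=0,
        plant_decoys=False,
        background_gene_fraction=0.0,
        background_effect_sd=0.0,
        batch_effect=0.0,
        sex_effect=0.0,
        age_effect=0.0,
        cell_composition_effect=0.0,
        composition_bystander_effect=0.0,
        chronic_pain_extra_shift=1.0,  # single shared generative process
        rng_seed=seed,
    )


def planted_dge_design(
    seed: int,
    n_genes: int = 5000,
    n_subjects: int = 20,
    n_de: int = 200,
    log2fc: float = 1.0,
) -> SimulationDesign:
    """A fully-paired cohort with n_de genes at +/-log2fc and nothing else."""
    d = null_dge_design(seed, n_genes, n_subjects)
    from dataclasses import replace

    return replace(d, planted_de_genes=n_de, de_log2fc=log2fc)
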