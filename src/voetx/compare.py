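"""Bootstrap-downsampling comparison of pathway enrichment between strata.

A small stratum (e.g. chronic-pain patients) can show more significant
pathways simply because small analyses are noisy. To test whether the
excess is real, subsets of the larger stratum are drawn with the *same*
steady-state / VOE sample sizes as the small stratum, the whole analysis
chain (paired DGE -> ranking -> GSEA) is recomputed on every subset, and
the observed significant-pathway count is compared against the subset
distribution (empirical exceedance p, floored at 1/(B+1), plus a normal
approximation). The mean NES over each analysis's own significant pathways
quantifies the enrichment magnitude; the percent excess compares the
observed stratum against the full comparison stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    DataValidationError,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    TimePoint,
    exclude_followup,
)
from .dge import (
    DGEResult,
    bh_adjust,
    estimate_consensus_correlation,
    fit_gene_models,
    moderate_variances,
)
from .enrichment import EnrichmentResult, gsea, rank_statistic


@dataclass
class SubsetDraw:
    sample_ids: list[str]
    with_replacement_ss: bool
    with_replacement_voe: bool
    seed: int


@dataclass
class DownsampleResult:
    count_observed: int
    counts_subsets: list[int]
    empirical_p: float
    normal_p: float
    mean_nes_observed_p05: float
    mean_nes_observed_p01: float
    mean_nes_subsets_p05: list[float]
    mean_nes_comparison_p05: float
    percent_nes_excess: float | None
    alpha: float
    subsets: list[SubsetDraw] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "count_observed": self.count_observed,
            "counts_subsets": self.counts_subsets,
            "empirical_p": self.empirical_p,
            "normal_p": self.normal_p,
            "mean_nes_observed_p05": self.mean_nes_observed_p05,
            "mean_nes_observed_p01": self.mean_nes_observed_p01,
            "mean_nes_subsets_p05": self.mean_nes_subsets_p05,
            "mean_nes_comparison_p05": self.mean_nes_comparison_p05,
            "percent_nes_excess": self.percent_nes_excess,
            "alpha": self.alpha,
            "subset_sample_ids": [s.sample_ids for s in self.subsets],
        }


def downsample_subsets(
    meta: Sequence[SampleMetadata],
    target_sizes: tuple[int, int],
    b: int = 30,
    seed: int = 0,
) -> list[SubsetDraw]:
    """Draw B subsets of the source samples matching (n_ss, n_voe).

    Within each time point, at most one sample per subject is used when the
    subject pool allows it; sampling is without replacement when the pool is
    large enough and with replacement (recorded on the draw) otherwise.
    """
    n_ss, n_voe = target_sizes
    if n_ss <= 0 or n_voe <= 0:
        raise DataValidationError("target sizes must be positive in both arms")
    meta = exclude_followup(meta)
    pools = {
        TimePoint.STEADY_STATE: [m for m in meta if m.time_point is TimePoint.STEADY_STATE],
        TimePoint.VOE: [m for m in meta if m.time_point is TimePoint.VOE],
    }
    for tp, pool in pools.items():
        if not pool:
            raise DataValidationError(f"source stratum has no {tp.value} samples")
    rng = np.random.default_rng(seed)
    draws: list[SubsetDraw] = []
    for i in range(b):
        chosen: list[str] = []
        repl: dict[TimePoint, bool] = {}
        for tp, target in ((TimePoint.STEADY_STATE, n_ss), (TimePoint.VOE, n_voe)):
            pool = pools[tp]
            by_subject: dict[str, list[str]] = {}
            for m in pool:
                by_subject.setdefault(m.subject_id, []).append(m.sample_id)
            subjects = sorted(by_subject)
            if len(subjects) >= target:
                picked = rng.choice(len(subjects), size=target, replace=False)
                repl[tp] = False
                for s in picked:
                    ids = by_subject[subjects[int(s)]]
                    chosen.append(ids[int(rng.integers(len(ids)))])
            elif len(pool) >= target:
                all_ids = sorted(m.sample_id for m in pool)
                picked = rng.choice(len(all_ids), size=target, replace=False)
                repl[tp] = False
                chosen.extend(all_ids[int(s)] for s in picked)
            else:
                all_ids = sorted(m.sample_id for m in pool)
                picked = rng.choice(len(all_ids), size=target, replace=True)
                repl[tp] = True
                chosen.extend(all_ids[int(s)] for s in picked)
        draws.append(
            SubsetDraw(
                sample_ids=chosen,
                with_replacement_ss=repl[TimePoint.STEADY_STATE],
                with_replacement_voe=repl[TimePoint.VOE],
                seed=seed + i,
            )
        )
    return draws


def _materialize_subset(
    em: ExpressionMatrix, meta: Sequence[SampleMetadata], sample_ids: Sequence[str]
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Build the subset expression/metadata, renaming repeated draws uniquely."""
    by_sample = {m.sample_id: m for m in meta}
    cols, new_ids, new_meta = [], [], []
    seen: dict[str, int] = {}
    for sid in sample_ids:
        n = seen.get(sid, 0)
        seen[sid] = n + 1
        new_id = sid if n == 0 else f"{sid}#rep{n}"
        new_ids.append(new_id)
        cols.append(em.values[:, em.sample_ids.index(sid)])
        src = by_sample[sid]
        new_meta.append(
            SampleMetadata(
                sample_id=new_id,
                subject_id=src.subject_id,
                time_point=src.time_point,
                chronic_pain=src.chronic_pain,
                sex=src.sex,
                age_category=src.age_category,
                batch=src.batch,
                metformin=src.metformin,
                cell_fraction=src.cell_fraction,
                extra=dict(src.extra),
            )
        )
    sub = ExpressionMatrix(list(em.gene_ids), new_ids, np.column_stack(cols))
    return sub, new_meta


def run_enrichment_chain(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    residual_df_loss: int = 0,
) -> tuple[DGEResult, EnrichmentResult]:
    """Paired DGE -> ranking -> GSEA on one sample set.

    ``residual_df_loss`` carries the degrees of freedom consumed by an
    upstream covariate adjustment. The within-subject correlation falls back
    to zero when the set contains fewer than three subjects sampled twice
    (typical for random subsets).
    """
    meta = [m for m in meta if m.sample_id in set(em.sample_ids)]
    try:
        rho = estimate_consensus_correlation(em, meta, residual_df_loss=residual_df_loss)
    except DataValidationError:
        rho = 0.0
    fits = fit_gene_models(em, meta, rho, residual_df_loss=residual_df_loss)
    mod = moderate_variances(fits)
    dge = DGEResult(
        gene_ids=mod.gene_ids,
        log2fc=mod.coef,
        amean=mod.amean,
        t=mod.t,
        df_total=mod.df_total,
        p=mod.p,
        adj_p=bh_adjust(mod.p),
        rho=rho.rho if hasattr(rho, "rho") else float(rho),
    )
    rl = rank_statistic(dge)
    enr = gsea(rl, gsc, n_perm=n_perm, seed=seed)
    return dge, enr


def enrichment_excess(
    observed: EnrichmentResult,
    subset_results: Sequence[EnrichmentResult],
    comparison: EnrichmentResult | None = None,
    alpha: float = 0.05,
    subsets: Sequence[SubsetDraw] = (),
) -> DownsampleResult:
    """Exceedance statistics of the observed stratum against the subset null."""
    if len(subset_results) < 2:
        raise DataValidationError("need at least 2 subset results")
    # counts and NES means are over VOE-elevated pathways (positive NES),
    # matching the study framing in which no significant pathway was
    # down-regulated in the stratum analyses
    count_obs = len(observed.significant(alpha, use_adjusted=True, positive_only=True))
    counts_b = [
        len(r.significant(alpha, use_adjusted=True, positive_only=True))
        for r in subset_results
    ]
    b = len(counts_b)
    empirical_p = (1.0 + sum(c >= count_obs for c in counts_b)) / (b + 1.0)
    mean_b = float(np.mean(counts_b))
    sd_b = float(np.std(counts_b, ddof=1))
    if sd_b > 0:
        normal_p = float(stats.norm.sf((count_obs - mean_b) / sd_b))
    else:
        normal_p = 1.0 if count_obs <= mean_b else 0.0

    mean_obs_05 = observed.mean_nes_significant(0.05, use_adjusted=False)
    mean_obs_01 = observed.mean_nes_significant(0.01, use_adjusted=False)
    mean_sub_05 = [r.mean_nes_significant(0.05, use_adjusted=False) for r in subset_results]
    if comparison is not None:
        mean_comp = comparison.mean_nes_significant(0.05, use_adjusted=False)
    else:
        mean_comp = float("nan")
    if np.isfinite(mean_comp) and mean_comp > 0 and np.isfinite(mean_obs_05):
        excess = 100.0 * (mean_obs_05 / mean_comp - 1.0)
    else:
        excess = None
    return DownsampleResult(
        count_observed=count_obs,
        counts_subsets=counts_b,
        empirical_p=float(empirical_p),
        normal_p=normal_p,
        mean_nes_observed_p05=float(mean_obs_05),
        mean_nes_observed_p01=float(mean_obs_01),
        mean_nes_subsets_p05=[float(v) for v in mean_sub_05],
        mean_nes_comparison_p05=float(mean_comp),
        percent_nes_excess=excess,
        alpha=alpha,
        subsets=list(subsets),
    )


def compare_strata(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    gsc: GeneSetCollection,
    target: str = "chronic_pain",
    b: int = 30,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    residual_df_loss: int = 0,
) -> DownsampleResult:
    """Full stratum comparison: observed (target) vs downsampled source subsets.

    ``target`` is "chronic_pain" or "no_chronic_pain"; the other stratum is
    the downsampling source. Every subset reruns the full DGE -> GSEA chain.
    """
    meta = exclude_followup(meta)
    if target == "chronic_pain":
        tgt = [m for m in meta if m.chronic_pain]
        src = [m for m in meta if not m.chronic_pain]
    elif target == "no_chronic_pain":
        tgt = [m for m in meta if not m.chronic_pain]
        src = [m for m in meta if m.chronic_pain]
    else:
        raise DataValidationError(f"unknown target stratum {target!r}")
    n_ss = sum(1 for m in tgt if m.time_point is TimePoint.STEADY_STATE)
    n_voe = sum(1 for m in tgt if m.time_point is TimePoint.VOE)
    if n_ss == 0 or n_voe == 0:
        raise DataValidationError("target stratum lacks one of the time points")

    em_tgt = em.subset_samples([m.sample_id for m in tgt])
    _, obs = run_enrichment_chain(
        em_tgt, tgt, gsc, n_perm=n_perm, seed=seed, residual_df_loss=residual_df_loss
    )
    em_src = em.subset_samples([m.sample_id for m in src])
    _, comp = run_enrichment_chain(
        em_src, src, gsc, n_perm=n_perm, seed=seed + 1, residual_df_loss=residual_df_loss
    )

    draws = downsample_subsets(src, (n_ss, n_voe), b=b, seed=seed + 2)
    subset_results = []
    for i, d in enumerate(draws):
        sub_em, sub_meta = _materialize_subset(em, src, d.sample_ids)
        _, enr = run_enrichment_chain(
            sub_em, sub_meta, gsc, n_perm=n_perm, seed=seed + 3 + i,
            residual_df_loss=residual_df_loss,
        )
        subset_results.append(enr)
    return enrichment_excess(obs, subset_results, comparison=comp, alpha=alpha, subsets=draws)
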