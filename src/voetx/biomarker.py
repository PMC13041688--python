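"""Longitudinal biomarker-panel selection, PC1 panel scoring and group tests.

A candidate VOE biomarker must (i) be significantly up-regulated during VOE
in the moderated paired DGE, (ii) belong to at least one gene set that is
itself significantly enriched with positive NES, and (iii) show a positive
per-patient VOE minus steady-state change in strictly more than half of the
subjects with samples at both time points. The selected panel is summarised
per sample by the first principal component of the standardized panel
submatrix, and the VOE / steady-state score separation is tested with a
pooled-variance two-sample t test. Plasma protein levels are compared with
the Wilcoxon rank-sum test (exact for small tie-free samples).
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
    metadata_by_sample,
)
from .dge import DGEResult
from .enrichment import EnrichmentResult


@dataclass
class PatientFoldChange:
    """Per-subject, per-gene VOE minus steady-state mean log2 change."""

    subject_id: str
    delta: np.ndarray  # aligned to the expression matrix's gene order
    n_voe: int
    n_ss: int


@dataclass
class BiomarkerPanel:
    gene_ids: list[str]
    n_subjects_up: dict[str, int]
    n_subjects_eligible: int
    pathway_membership: dict[str, list[str]]
    warnings: list[str] = field(default_factory=list)


@dataclass
class PanelScore:
    sample_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    panel_genes: list[str]
    variance_explained: float


def patient_fold_changes(
    em: ExpressionMatrix, meta: Sequence[SampleMetadata]
) -> tuple[list[PatientFoldChange], list[str]]:
    """Per-subject mean(VOE) - mean(steady state), for paired subjects only.

    Returns the fold-change records and the ids of subjects excluded for
    lacking one of the two time points. Follow-up samples are ignored.
    """
    by_sample = metadata_by_sample(meta)
    cols: dict[str, dict[TimePoint, list[int]]] = {}
    for j, sid in enumerate(em.sample_ids):
        if sid not in by_sample:
            continue
        m = by_sample[sid]
        if m.time_point is TimePoint.FOLLOWUP:
            continue
        cols.setdefault(m.subject_id, {}).setdefault(m.time_point, []).append(j)
    out: list[PatientFoldChange] = []
    excluded: list[str] = []
    for subject in sorted(cols):
        tps = cols[subject]
        if TimePoint.VOE in tps and TimePoint.STEADY_STATE in tps:
            voe = em.values[:, tps[TimePoint.VOE]].mean(axis=1)
            ss = em.values[:, tps[TimePoint.STEADY_STATE]].mean(axis=1)
            out.append(
                PatientFoldChange(
                    subject_id=subject,
                    delta=voe - ss,
                    n_voe=len(tps[TimePoint.VOE]),
                    n_ss=len(tps[TimePoint.STEADY_STATE]),
                )
            )
        else:
            excluded.append(subject)
    if not out:
        raise DataValidationError("no subjects have samples at both time points")
    return out, excluded


def select_biomarkers(
    pfc: Sequence[PatientFoldChange],
    dge: DGEResult,
    gsea_result: EnrichmentResult,
    gsc: GeneSetCollection,
    alpha: float = 0.05,
) -> BiomarkerPanel:
    """Select the genes satisfying all three panel criteria (see module docs)."""
    warnings: list[str] = []
    sig_sets = [s.name for s in gsea_result.sets if s.adj_p < alpha and s.nes > 0]
    if not sig_sets:
        warnings.append("no significantly enriched gene sets; panel is empty")
    gene_to_sets: dict[str, list[str]] = {}
    for name in sig_sets:
        for g in gsc.genes(name):
            gene_to_sets.setdefault(g, []).append(name)

    n_eligible = len(pfc)
    majority = n_eligible / 2.0  # strictly more than half
    deltas = np.vstack([p.delta for p in pfc])  # subjects x genes

    selected: list[str] = []
    n_up: dict[str, int] = {}
    membership: dict[str, list[str]] = {}
    for i, g in enumerate(dge.gene_ids):
        if not (dge.adj_p[i] < alpha and dge.log2fc[i] > 0):
            continue
        if g not in gene_to_sets:
            continue
        up = int(np.sum(deltas[:, i] > 0))
        if up > majority:
            selected.append(g)
            n_up[g] = up
            membership[g] = gene_to_sets[g]
    return BiomarkerPanel(
        gene_ids=selected,
        n_subjects_up=n_up,
        n_subjects_eligible=n_eligible,
        pathway_membership=membership,
        warnings=warnings,
    )


def pc1_scores(em: ExpressionMatrix, panel_genes: Sequence[str]) -> PanelScore:
    """PC1 of the standardized panel submatrix, oriented to positive loading sum."""
    if len(panel_genes) < 2:
        raise DataValidationError("need at least 2 panel genes")
    if len(em.sample_ids) < 3:
        raise DataValidationError("need at least 3 samples")
    rows = []
    for g in panel_genes:
        if g not in em.gene_ids:
            raise DataValidationError(f"panel gene {g!r} absent from expression matrix")
        x = em.gene_row(g).astype(float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise DataValidationError(f"panel gene {g!r} is constant across samples")
        rows.append((x - x.mean()) / sd)
    x = np.vstack(rows)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = u[:, 0]
    scores = s[0] * vt[0]
    if loadings.sum() <= 0:
        loadings, scores = -loadings, -scores
    return PanelScore(
        sample_ids=list(em.sample_ids),
        scores=scores,
        loadings=loadings,
        panel_genes=list(panel_genes),
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
    )


def group_difference_test(
    scores: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Pooled-variance two-sample t test between the two group labels present."""
    scores = np.asarray(scores, dtype=float)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise DataValidationError(f"need exactly 2 group labels, got {labels}")
    mask = np.array([g == labels[0] for g in groups])
    x, y = scores[mask], scores[~mask]
    if len(x) < 2 or len(y) < 2:
        raise DataValidationError("need at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when min(n_x, n_y) <= 8 and there are no ties;
    otherwise a normal approximation with tie and continuity corrections.
    Returns (rank sum of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U_x -> rank sum of x
    return w, float(res.pvalue)
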