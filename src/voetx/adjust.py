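"""Cell-composition axis scores and fixed-effect covariate removal.

The leukocyte fraction mixes T cells, B cells and other populations whose
proportions differ between samples; a small panel of axis marker genes
("blood informative transcripts") summarises each population's abundance
as the first principal component of the standardized marker submatrix.
Those axis scores, together with age category, sex, batch, pain status and
metformin use, are removed gene-by-gene with ordinary least squares while
the time-point (steady state vs VOE) signal is explicitly retained: the
fitted contribution of the *centered* nuisance columns is subtracted, so
the biological coefficient is unchanged and refitting any nuisance
covariate on the adjusted values returns a zero coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DataValidationError,
    ExpressionMatrix,
    SampleMetadata,
    TimePoint,
    metadata_by_sample,
)


@dataclass
class AxisScore:
    """PC1 summary of a marker-gene panel, one score per sample."""

    axis_name: str
    sample_ids: list[str]
    scores: np.ndarray  # mean zero across samples
    loadings: np.ndarray  # one per marker gene, sum > 0 by orientation rule
    marker_genes: list[str]
    variance_explained: float


@dataclass
class AdjustedExpression:
    expression: ExpressionMatrix
    biological_variable: str
    adjustment_variables: list[str]
    nuisance_coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    # residual degrees of freedom consumed by the removed nuisance columns;
    # downstream variance estimates must subtract these
    n_nuisance_dims: int = 0


def axis_score(
    em: ExpressionMatrix, marker_genes: Sequence[str], axis_name: str
) -> AxisScore:
    """PC1 score of a marker panel across samples.

    Marker rows are centered and unit-scaled across samples before the SVD;
    the sign is flipped when the loading sum is non-positive so that higher
    scores mean higher marker expression.
    """
    if len(em.sample_ids) < 2:
        raise DataValidationError("axis_score needs at least 2 samples")
    rows = []
    for g in marker_genes:
        if g not in em.gene_ids:
            raise DataValidationError(f"marker gene {g!r} absent from expression matrix")
        x = em.gene_row(g).astype(float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise DataValidationError(f"marker gene {g!r} is constant across samples")
        rows.append((x - x.mean()) / sd)
    x = np.vstack(rows)  # genes x samples, standardized
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = u[:, 0]
    scores = s[0] * vt[0]
    if loadings.sum() <= 0:
        loadings, scores = -loadings, -scores
    return AxisScore(
        axis_name=axis_name,
        sample_ids=list(em.sample_ids),
        scores=scores,
        loadings=loadings,
        marker_genes=list(marker_genes),
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
    )


def _one_hot(labels: Sequence[str], name: str) -> tuple[np.ndarray, list[str]]:
    """Reference-level one-hot encoding; first level (sorted) is the reference."""
    levels = sorted(set(labels))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append(np.array([1.0 if l == lev else 0.0 for l in labels]))
        names.append(f"{name}[{lev}]")
    if not cols:
        return np.empty((len(labels), 0)), []
    return np.column_stack(cols), names


def build_design(
    meta: Sequence[SampleMetadata],
    sample_ids: Sequence[str],
    axis_scores: Sequence[AxisScore] = (),
    adjust_for: Sequence[str] = ("age_category", "sex", "batch", "chronic_pain", "metformin"),
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Encode the design: (biological columns, names, nuisance columns, names).

    The biological variable is the time point (reference: steady state).
    Categorical nuisance covariates are one-hot with a reference level; axis
    scores enter centered.
    """
    by_sample = metadata_by_sample(meta)
    missing = [s for s in sample_ids if s not in by_sample]
    if missing:
        raise DataValidationError(f"samples missing metadata: {missing[:5]}")
    recs = [by_sample[s] for s in sample_ids]

    tp_order = [TimePoint.STEADY_STATE, TimePoint.VOE, TimePoint.FOLLOWUP]
    present = [t for t in tp_order if any(r.time_point is t for r in recs)]
    bio_cols, bio_names = [], []
    for t in present[1:]:
        bio_cols.append(np.array([1.0 if r.time_point is t else 0.0 for r in recs]))
        bio_names.append(f"time_point[{t.value}]")
    bio = np.column_stack(bio_cols) if bio_cols else np.empty((len(recs), 0))

    nuis_cols: list[np.ndarray] = []
    nuis_names: list[str] = []
    getters = {
        "age_category": lambda r: r.age_category.value,
        "sex": lambda r: r.sex.value,
        "batch": lambda r: r.batch,
        "chronic_pain": lambda r: str(r.chronic_pain),
        "metformin": lambda r: str(r.metformin),
    }
    for var in adjust_for:
        if var not in getters:
            raise DataValidationError(f"unknown adjustment variable {var!r}")
        block, names = _one_hot([getters[var](r) for r in recs], var)
        if block.shape[1]:
            nuis_cols.append(block)
            nuis_names.extend(names)
    for ax in axis_scores:
        order = [ax.sample_ids.index(s) for s in sample_ids]
        col = ax.scores[order]
        nuis_cols.append((col - col.mean())[:, np.newaxis])
        nuis_names.append(f"axis[{ax.axis_name}]")
    nuis = np.column_stack(nuis_cols) if nuis_cols else np.empty((len(recs), 0))
    return bio, bio_names, nuis, nuis_names


def supervised_adjust(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    axis_scores: Sequence[AxisScore] = (),
    adjust_for: Sequence[str] = ("age_category", "sex", "batch", "chronic_pain", "metformin"),
    collinearity_tol: float = 1e-8,
) -> AdjustedExpression:
    """Remove fixed-effect nuisance covariates while keeping the time-point signal.

    Per gene: fit OLS on [intercept | time point | nuisance]; subtract the
    fitted contribution of the mean-centered nuisance columns. The
    time-point coefficient of the adjusted data equals the original to
    numerical precision, and refitting nuisance covariates yields ~0.
    """
    bio, bio_names, nuis, nuis_names = build_design(meta, em.sample_ids, axis_scores, adjust_for)
    n = len(em.sample_ids)
    intercept = np.ones((n, 1))
    x = np.hstack([intercept, bio, nuis])
    names = ["intercept", *bio_names, *nuis_names]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = _aliased_columns(x, names)
        raise DataValidationError(f"rank-deficient design; aliased columns: {aliased}")
    if bio.shape[1]:
        # biological variable must not be (nearly) explained by the nuisance block
        q, _ = np.linalg.qr(np.hstack([intercept, nuis]))
        resid = bio - q @ (q.T @ bio)
        if np.any(np.sum(resid**2, axis=0) < collinearity_tol * np.sum(bio**2, axis=0)):
            raise DataValidationError(
                "time point is collinear with the adjustment covariates"
            )
    beta, *_ = np.linalg.lstsq(x, em.values.T, rcond=None)  # (p, genes)
    n_bio = bio.shape[1]
    nuis_centered = nuis - nuis.mean(axis=0, keepdims=True)
    beta_nuis = beta[1 + n_bio :, :]
    adjusted = em.values - (nuis_centered @ beta_nuis).T
    coefs = {name: beta[1 + n_bio + j, :].copy() for j, name in enumerate(nuis_names)}
    return AdjustedExpression(
        expression=ExpressionMatrix(list(em.gene_ids), list(em.sample_ids), adjusted),
        biological_variable="time_point",
        adjustment_variables=list(nuis_names),
        nuisance_coefficients=coefs,
        n_nuisance_dims=nuis.shape[1],
    )


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    kept = np.empty((x.shape[0], 0))
    for j in range(x.shape[1]):
        cand = np.hstack([kept, x[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(names[j])
        else:
            kept = cand
    return aliased
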