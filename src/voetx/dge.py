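"""Paired moderated differential expression between steady state and VOE.

Subjects contribute samples at both time points, so observations are not
independent: a consensus within-subject correlation is estimated from the
residuals of all genes (a trimmed Fisher-z average standing in for REML),
and each gene is then fit by generalized least squares under a
block-equicorrelated covariance (correlation rho within subject, zero
between). Residual variances are shrunk toward a smooth mean-variance
trend by empirical Bayes, giving moderated t statistics with augmented
degrees of freedom, and Benjamini-Hochberg step-up controls the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.linalg import solve_triangular
from statsmodels.nonparametric.smoothers_lowess import lowess

from .adjust import build_design
from .core import (
    DataValidationError,
    ExpressionMatrix,
    PipelineConfig,
    SampleMetadata,
    TimePoint,
    exclude_followup,
    metadata_by_sample,
)


@dataclass
class ConsensusCorrelation:
    rho: float
    per_gene: np.ndarray
    trim: float = 0.10


@dataclass
class GeneFits:
    gene_ids: list[str]
    coef: np.ndarray  # VOE - steady state log2FC
    stdev_unscaled: np.ndarray  # se / residual sd, one per gene (equal here)
    sigma2: np.ndarray  # residual variance s^2
    df_residual: float
    amean: np.ndarray  # average log2 expression per gene
    n_single_timepoint_subjects: int = 0


@dataclass
class ModeratedFits:
    gene_ids: list[str]
    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float
    s2_post: np.ndarray
    s2_prior: np.ndarray
    df_prior: float
    amean: np.ndarray


@dataclass
class DGEResult:
    """Per-gene moderated paired differential expression table."""

    gene_ids: list[str]
    log2fc: np.ndarray
    amean: np.ndarray
    t: np.ndarray
    df_total: float
    p: np.ndarray
    adj_p: np.ndarray
    rho: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2FC": self.log2fc,
                "A": self.amean,
                "t": self.t,
                "df": self.df_total,
                "p": self.p,
                "adj_p": self.adj_p,
            }
        )

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [g for g, q in zip(self.gene_ids, self.adj_p) if q < alpha]


# ---------------------------------------------------------------------------
# Consensus within-subject correlation
# ---------------------------------------------------------------------------


def estimate_consensus_correlation(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    trim: float = 0.10,
    residual_df_loss: int = 0,
) -> ConsensusCorrelation:
    """Trimmed Fisher-z consensus of per-gene within-subject residual correlations.

    Per gene the expression is residualized on the fixed design (intercept +
    time point); the average product of residual pairs within a subject,
    scaled by the residual variance, estimates that gene's intra-subject
    correlation. Fisher-z values are trimmed 10% per tail, averaged, and the
    back-transformed consensus capped at +/-0.99.
    """
    by_sample = metadata_by_sample(meta)
    subjects = [by_sample[s].subject_id for s in em.sample_ids]
    counts: dict[str, int] = {}
    for s in subjects:
        counts[s] = counts.get(s, 0) + 1
    multi = [s for s, c in counts.items() if c >= 2]
    if len(multi) < 3:
        raise DataValidationError(
            "fewer than 3 subjects with repeated samples; use an unpaired analysis"
        )
    bio, _, _, _ = build_design(meta, em.sample_ids, adjust_for=())
    x = np.hstack([np.ones((len(subjects), 1)), bio])
    y = em.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    e = y - x @ beta  # samples x genes
    df = len(subjects) - x.shape[1] - residual_df_loss
    s2 = np.sum(e**2, axis=0) / df
    s2 = np.maximum(s2, 1e-300)

    pair_sum = np.zeros(e.shape[1])
    n_pairs = 0
    for subj in multi:
        idx = [i for i, s in enumerate(subjects) if s == subj]
        block = e[idx]  # m x genes
        m = len(idx)
        pair_sum += (block.sum(axis=0) ** 2 - (block**2).sum(axis=0)) / 2.0
        n_pairs += m * (m - 1) // 2
    per_gene = pair_sum / (n_pairs * s2)
    # first-order small-sample bias correction: the OLS residual projection
    # attenuates within-subject products by (1 - 1/S) for S paired subjects
    per_gene = per_gene * len(multi) / (len(multi) - 1)
    per_gene = np.clip(per_gene, -0.999, 0.999)
    z = np.arctanh(per_gene)
    consensus = float(np.tanh(stats.trim_mean(z, trim)))
    consensus = float(np.clip(consensus, -0.99, 0.99))
    return ConsensusCorrelation(rho=consensus, per_gene=per_gene, trim=trim)


# ---------------------------------------------------------------------------
# Generalized least squares under block equicorrelation
# ---------------------------------------------------------------------------


def _block_covariance(subjects: Sequence[str], rho: float) -> np.ndarray:
    n = len(subjects)
    subj = np.asarray(subjects)
    v = (subj[:, None] == subj[None, :]).astype(float) * rho
    np.fill_diagonal(v, 1.0)
    return v


def fit_gene_models(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    rho: ConsensusCorrelation | float = 0.0,
    adjust_for: Sequence[str] = (),
    residual_df_loss: int = 0,
) -> GeneFits:
    """GLS fit of every gene on [intercept | time point (| covariates)].

    The covariance is block-equicorrelated by subject. Subjects observed at
    a single time point still enter (the covariance handles them) but are
    tallied as a warning count. The reported coefficient is the VOE minus
    steady-state contrast.
    """
    r = rho.rho if isinstance(rho, ConsensusCorrelation) else float(rho)
    by_sample = metadata_by_sample(meta)
    subjects = [by_sample[s].subject_id for s in em.sample_ids]
    tps = [by_sample[s].time_point for s in em.sample_ids]
    if not ({TimePoint.STEADY_STATE, TimePoint.VOE} <= set(tps)):
        raise DataValidationError("need samples at both steady state and VOE")
    bio, bio_names, nuis, _ = build_design(meta, em.sample_ids, adjust_for=adjust_for)
    x = np.hstack([np.ones((len(subjects), 1)), bio, nuis])
    contrast_idx = 1 + bio_names.index("time_point[voe]")

    single = 0
    tp_by_subj: dict[str, set[TimePoint]] = {}
    for s, t in zip(subjects, tps):
        tp_by_subj.setdefault(s, set()).add(t)
    single = sum(1 for v in tp_by_subj.values() if len(v) == 1)

    if r != 0.0:
        v = _block_covariance(subjects, r)
        l = np.linalg.cholesky(v)
        xw = solve_triangular(l, x, lower=True)
        yw = solve_triangular(l, em.values.T, lower=True)
    else:
        xw, yw = x, em.values.T

    q, rr = np.linalg.qr(xw)
    beta = np.linalg.solve(rr, q.T @ yw)  # p x genes
    resid = yw - xw @ beta
    df = xw.shape[0] - xw.shape[1] - residual_df_loss
    if df <= 0:
        raise DataValidationError("non-positive residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = np.linalg.inv(rr.T @ rr)
    unscaled = float(np.sqrt(xtx_inv[contrast_idx, contrast_idx]))
    return GeneFits(
        gene_ids=list(em.gene_ids),
        coef=beta[contrast_idx],
        stdev_unscaled=np.full(len(em.gene_ids), unscaled),
        sigma2=sigma2,
        df_residual=float(df),
        amean=em.values.mean(axis=1),
        n_single_timepoint_subjects=single,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation with a mean-variance trend
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(fits: GeneFits, trend: bool = True, span: float = 0.5) -> ModeratedFits:
    """Empirical-Bayes shrinkage of residual variances toward a trend in A.

    A lowess curve through {A, log s^2} gives the prior variance s0^2(A);
    the prior degrees of freedom d0 come from matching the observed spread
    of log(s^2/s0^2) to the theoretical log-F variance. The posterior
    variance is the d0/d weighted blend and the moderated t uses d0 + d
    degrees of freedom.
    """
    if len(fits.gene_ids) < 10:
        raise DataValidationError("need at least 10 genes for variance moderation")
    s2 = np.asarray(fits.sigma2, dtype=float)
    if np.all(s2 == 0):
        raise DataValidationError("all residual variances are zero")
    s2 = np.maximum(s2, 1e-300)
    d = fits.df_residual
    logs2 = np.log(s2)
    if trend:
        fitvals = lowess(
            logs2, fits.amean, frac=span, it=3, xvals=np.asarray(fits.amean, dtype=float)
        )
        log_s0 = np.asarray(fitvals, dtype=float)
    else:
        log_s0 = np.full_like(logs2, logs2.mean())

    z = logs2 - log_s0
    # log F(d, d0) moments: mean psi(d/2)-psi(d0/2)+log(d0/d), var psi'(d/2)+psi'(d0/2)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        mean_shift = float(np.mean(z)) - (
            float(special.digamma(d / 2.0))
            - float(special.digamma(d0 / 2.0))
            + np.log(d0 / d)
        )
    else:
        d0 = np.inf
        # s^2 ~ s0^2 chi2_d / d when d0 = inf
        mean_shift = float(np.mean(z)) - (
            float(special.digamma(d / 2.0)) - np.log(d / 2.0)
        )
    s2_prior = np.exp(log_s0 + mean_shift)

    if np.isinf(d0):
        s2_post = s2_prior.copy()
        df_total = np.inf
    else:
        s2_post = (d0 * s2_prior + d * s2) / (d0 + d)
        df_total = d0 + d
    t = fits.coef / (fits.stdev_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedFits(
        gene_ids=list(fits.gene_ids),
        coef=fits.coef,
        t=t,
        p=p,
        df_total=float(df_total) if np.isfinite(df_total) else np.inf,
        s2_post=s2_post,
        s2_prior=s2_prior,
        df_prior=float(d0) if np.isfinite(d0) else np.inf,
        amean=fits.amean,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, reported in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_dge(
    em,
    meta: Sequence[SampleMetadata],
    config: PipelineConfig | None = None,
    adjust_for: Sequence[str] = (),
    trend: bool = True,
    include_followup: bool = False,
) -> DGEResult:
    """Full paired DGE chain: consensus rho -> GLS -> moderation -> BH.

    ``em`` may be an :class:`ExpressionMatrix` or an ``AdjustedExpression``;
    in the latter case the residual degrees of freedom spent by the upstream
    covariate removal are subtracted from every variance estimate. Follow-up
    samples are excluded by default; the analysis is deterministic given its
    inputs.
    """
    df_loss = 0
    if hasattr(em, "expression"):  # AdjustedExpression
        df_loss = int(getattr(em, "n_nuisance_dims", 0))
        em = em.expression
    meta = exclude_followup(meta, include_followup)
    keep = [s for s in em.sample_ids if s in {m.sample_id for m in meta}]
    if keep != list(em.sample_ids):
        em = em.subset_samples(keep)
    rho = estimate_consensus_correlation(em, meta, residual_df_loss=df_loss)
    fits = fit_gene_models(em, meta, rho, adjust_for=adjust_for, residual_df_loss=df_loss)
    mod = moderate_variances(fits, trend=trend)
    adj = bh_adjust(mod.p)
    return DGEResult(
        gene_ids=mod.gene_ids,
        log2fc=mod.coef,
        amean=mod.amean,
        t=mod.t,
        df_total=mod.df_total,
        p=mod.p,
        adj_p=adj,
        rho=rho.rho,
    )
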