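"""Gene filtering, TMM normalization and log-CPM transformation.

TMM (trimmed mean of M-values) corrects between-sample library composition
bias: for each sample a log-ratio (M) / log-abundance (A) trimmed, weighted
mean against a reference sample gives a scaling factor applied to the raw
library size. Factors are rescaled to geometric mean one so that the overall
scale of the data is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    SampleMetadata,
    Sex,
    metadata_by_sample,
)


@dataclass
class NormalizationFactors:
    sample_ids: list[str]
    tmm_factors: np.ndarray  # positive, geometric mean 1
    library_sizes: np.ndarray  # raw column sums
    reference_sample: str

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors


def filter_low_expression(cm: CountMatrix, zero_fraction: float = 0.10) -> CountMatrix:
    """Remove genes with zero counts in at least ``zero_fraction`` of samples.

    A gene is retained iff its fraction of zero-count samples is strictly
    below the threshold; the sample set is unchanged.
    """
    if not (0.0 < zero_fraction <= 1.0):
        raise DataValidationError("zero_fraction must be in (0, 1]")
    n = len(cm.sample_ids)
    frac_zero = (cm.counts == 0).sum(axis=1) / n
    keep = frac_zero < zero_fraction
    if not keep.any():
        raise DataValidationError(
            "filtering removed every gene; review the zero-fraction threshold"
        )
    gene_ids = [g for g, k in zip(cm.gene_ids, keep) if k]
    return CountMatrix(gene_ids, list(cm.sample_ids), cm.counts[keep])


def _choose_reference(cm: CountMatrix) -> int:
    """Sample whose 75th-percentile count fraction is closest to the mean of those.

    Ties broken by the lexicographically first sample id, for determinism.
    """
    lib = cm.library_sizes()
    q75 = np.quantile(cm.counts / lib[np.newaxis, :], 0.75, axis=0)
    dist = np.abs(q75 - q75.mean())
    best = np.flatnonzero(dist == dist.min())
    if len(best) > 1:
        ids = [cm.sample_ids[i] for i in best]
        return int(best[int(np.argmin(ids))])
    return int(best[0])


def _tmm_pair(
    y_k: np.ndarray,
    y_r: np.ndarray,
    n_k: float,
    n_r: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    pos = (y_k > 0) & (y_r > 0)
    yk, yr = y_k[pos].astype(float), y_r[pos].astype(float)
    m = np.log2((yk / n_k) / (yr / n_r))
    a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
    lo_m, hi_m = np.quantile(m, [logratio_trim, 1.0 - logratio_trim])
    lo_a, hi_a = np.quantile(a, [abs_trim, 1.0 - abs_trim])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() < 10:
        raise DataValidationError(
            f"only {int(keep.sum())} genes survive TMM trimming; need >= 10"
        )
    # asymptotic (delta-method) variance of M; inverse-variance weights
    var = (n_k - yk[keep]) / (n_k * yk[keep]) + (n_r - yr[keep]) / (n_r * yr[keep])
    w = 1.0 / var
    log2f = float(np.sum(w * m[keep]) / np.sum(w))
    return 2.0**log2f


def tmm_factors(
    cm: CountMatrix, logratio_trim: float = 0.30, abs_trim: float = 0.05
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1."""
    lib = cm.library_sizes()
    if np.any(lib <= 0):
        bad = cm.sample_ids[int(np.argmax(lib <= 0))]
        raise DataValidationError(f"sample {bad!r} has zero library size")
    ref = _choose_reference(cm)
    y_r, n_r = cm.counts[:, ref], lib[ref]
    factors = np.ones(len(cm.sample_ids))
    for k in range(len(cm.sample_ids)):
        if k == ref:
            continue
        factors[k] = _tmm_pair(cm.counts[:, k], y_r, lib[k], n_r, logratio_trim, abs_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=list(cm.sample_ids),
        tmm_factors=factors,
        library_sizes=lib,
        reference_sample=cm.sample_ids[ref],
    )


def log_cpm(
    cm: CountMatrix, nf: NormalizationFactors, prior_count: float = 0.5
) -> ExpressionMatrix:
    """log2 counts per million against TMM-effective library sizes.

    value = log2((count + prior) / (effective library + 2*prior) * 1e6).
    The prior keeps zero counts finite.
    """
    if list(cm.sample_ids) != list(nf.sample_ids):
        order = [nf.sample_ids.index(s) for s in cm.sample_ids]
        eff = nf.effective_library_sizes[order]
    else:
        eff = nf.effective_library_sizes
    if np.any(eff <= 0):
        raise DataValidationError("non-positive effective library size")
    vals = np.log2(
        (cm.counts + prior_count) / (eff[np.newaxis, :] + 2.0 * prior_count) * 1e6
    )
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), vals)


@dataclass
class SexConcordance:
    sample_id: str
    inferred: Sex
    recorded: Sex
    concordant: bool


def verify_sex(
    em: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    xist_id: str = "XIST",
    rps4y1_id: str = "RPS4Y1",
) -> list[SexConcordance]:
    """Check recorded sex against XIST (female) vs RPS4Y1 (male) expression.

    A sample is inferred female when XIST exceeds RPS4Y1 on the log scale.
    Metadata is never mutated; mismatches are only flagged.
    """
    for g in (xist_id, rps4y1_id):
        if g not in em.gene_ids:
            raise DataValidationError(f"sex marker gene {g!r} absent from expression matrix")
    xist = em.gene_row(xist_id)
    rps4y1 = em.gene_row(rps4y1_id)
    by_sample = metadata_by_sample(meta)
    report = []
    for j, sid in enumerate(em.sample_ids):
        if sid not in by_sample:
            continue
        inferred = Sex.F if xist[j] > rps4y1[j] else Sex.M
        recorded = by_sample[sid].sex
        report.append(SexConcordance(sid, inferred, recorded, inferred == recorded))
    return report
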