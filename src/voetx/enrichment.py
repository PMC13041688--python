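"""Gene-set enrichment: ranked running-sum ES/NES and per-sample pathway scores.

Genes are ranked by -log10(adjusted p) * log2(fold change), so strongly and
significantly up-regulated genes lead the list. For each gene set a weighted
Kolmogorov-Smirnov-like running sum walks the ranking, stepping up by
|statistic|^p (normalized) at in-set genes and down by 1/(N-k) elsewhere;
the signed extremum of larger magnitude is the enrichment score. Null ES
distributions come from uniformly random gene sets of matched size under a
fixed seed; NES divides ES by the mean same-sign null magnitude.

Per-sample scores follow the gene-set variation approach: a Gaussian-kernel
ECDF per gene, a symmetric within-sample rank statistic, and the same
weighted walk evaluated per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import DataValidationError, ExpressionMatrix, GeneSetCollection
from .dge import DGEResult, bh_adjust

_ADJP_FLOOR = 1e-300


@dataclass
class RankedList:
    """Genes sorted by descending ranking statistic (ties: lexicographic id)."""

    gene_ids: list[str]
    statistics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.statistics):
            raise DataValidationError("ranked list length mismatch")


@dataclass
class SetEnrichment:
    name: str
    size: int
    es: float
    nes: float
    p: float
    adj_p: float
    leading_edge: list[str]


@dataclass
class EnrichmentResult:
    sets: list[SetEnrichment]
    skipped: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": [s.name for s in self.sets],
                "size": [s.size for s in self.sets],
                "ES": [s.es for s in self.sets],
                "NES": [s.nes for s in self.sets],
                "p": [s.p for s in self.sets],
                "adj_p": [s.adj_p for s in self.sets],
                "leading_edge": [";".join(s.leading_edge) for s in self.sets],
            }
        )

    def significant(
        self,
        alpha: float = 0.05,
        use_adjusted: bool = True,
        positive_only: bool = False,
    ) -> list[SetEnrichment]:
        key = (lambda s: s.adj_p) if use_adjusted else (lambda s: s.p)
        sets = [s for s in self.sets if key(s) < alpha]
        if positive_only:
            sets = [s for s in sets if s.nes > 0]
        return sets

    def mean_nes_significant(
        self,
        alpha: float = 0.05,
        use_adjusted: bool = False,
        positive_only: bool = True,
    ) -> float:
        """Mean NES over the significantly enriched (by default, elevated) sets."""
        sig = self.significant(alpha, use_adjusted, positive_only)
        if not sig:
            return float("nan")
        return float(np.mean([s.nes for s in sig]))


@dataclass
class SampleScoreMatrix:
    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # sets x samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def zscores(self) -> np.ndarray:
        """Per-set z-scores across samples (for heatmap-style reporting)."""
        mu = self.scores.mean(axis=1, keepdims=True)
        sd = self.scores.std(axis=1, ddof=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (self.scores - mu) / sd


def rank_statistic(dge: DGEResult) -> RankedList:
    """-log10(adjusted p) * log2FC, sorted descending; ties broken by gene id."""
    adj = np.maximum(np.asarray(dge.adj_p, dtype=float), _ADJP_FLOOR)
    r = -np.log10(adj) * np.asarray(dge.log2fc, dtype=float)
    order = sorted(range(len(r)), key=lambda i: (-r[i], dge.gene_ids[i]))
    return RankedList([dge.gene_ids[i] for i in order], r[order])


def enrichment_score(
    rl: RankedList, set_genes: Sequence[str], weight: float = 1.0
) -> tuple[float, list[str], tuple[int, int]]:
    """Weighted running-sum ES for one gene set against a ranked list.

    Returns (ES, leading-edge gene ids, (argmax, argmin) walk positions).
    """
    universe = rl.gene_ids
    n = len(universe)
    members = set(set_genes)
    mask = np.array([g in members for g in universe])
    k = int(mask.sum())
    if k == 0:
        raise DataValidationError("gene set has empty intersection with the universe")
    if k == n:
        raise DataValidationError("gene set covers the whole universe")
    absr = np.abs(rl.statistics) ** weight
    nr = float(absr[mask].sum())
    inc = np.where(mask, (absr / nr) if nr > 0 else (mask / k), -1.0 / (n - k))
    walk = np.cumsum(inc)
    imax = int(np.argmax(walk))
    imin = int(np.argmin(walk))
    pos, neg = float(walk[imax]), float(walk[imin])
    if max(pos, 0.0) >= max(-neg, 0.0):
        es = pos
        leading = [universe[i] for i in range(imax + 1) if mask[i]]
    else:
        es = neg
        leading = [universe[i] for i in range(imin, n) if mask[i]]
    return es, leading, (imax, imin)


def _walk_es_batch(mask: np.ndarray, absr: np.ndarray) -> np.ndarray:
    """Signed ES for a batch of boolean membership masks (rows) over one ranking."""
    n = mask.shape[1]
    k = mask.sum(axis=1, keepdims=True).astype(float)
    num = np.where(mask, absr[np.newaxis, :], 0.0)
    nr = num.sum(axis=1, keepdims=True)
    safe_nr = np.where(nr > 0, nr, 1.0)
    inc = np.where(mask, num / safe_nr, -1.0 / (n - k))
    # degenerate all-zero in-set stats: fall back to unweighted steps
    deg = (nr <= 0).ravel()
    if deg.any():
        inc[deg] = np.where(mask[deg], 1.0 / k[deg], -1.0 / (n - k[deg]))
    walk = np.cumsum(inc, axis=1)
    pos = walk.max(axis=1)
    neg = walk.min(axis=1)
    return np.where(np.maximum(pos, 0.0) >= np.maximum(-neg, 0.0), pos, neg)


def gsea(
    rl: RankedList,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Permutation GSEA over a gene-set collection.

    Null distributions use ``n_perm`` uniformly random same-size gene sets
    (prefixes of shared random permutations of the universe, drawn once from
    the seed, so results do not depend on gene-set file order). p-values and
    NES are computed against the same-sign half of the null.
    """
    if n_perm < 100:
        raise DataValidationError("n_perm must be >= 100")
    universe = rl.gene_ids
    n = len(universe)
    index = {g: i for i, g in enumerate(universe)}
    absr = np.abs(rl.statistics) ** weight

    sizes_needed: dict[str, int] = {}
    skipped: dict[str, str] = {}
    members_by_set: dict[str, np.ndarray] = {}
    for name in gsc.names():
        idx = np.array(sorted(index[g] for g in gsc.genes(name) if g in index), dtype=int)
        if idx.size == 0:
            skipped[name] = "no overlap with the ranked universe"
            continue
        if idx.size >= n:
            skipped[name] = "set covers the whole universe"
            continue
        members_by_set[name] = idx
        sizes_needed[name] = idx.size

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)

    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes_needed.values())):
        mask = np.zeros((n_perm, n), dtype=bool)
        rows = np.repeat(np.arange(n_perm), k)
        mask[rows, perms[:, :k].ravel()] = True
        null_by_size[k] = _walk_es_batch(mask, absr)

    records: list[SetEnrichment] = []
    for name, idx in members_by_set.items():
        es, leading, _ = enrichment_score(rl, [universe[i] for i in idx], weight)
        null = null_by_size[idx.size]
        if es >= 0:
            same = null[null >= 0]
            exceed = int(np.sum(same >= es))
        else:
            same = null[null < 0]
            exceed = int(np.sum(same <= es))
        p = (1.0 + exceed) / (1.0 + same.size)
        denom = float(np.mean(np.abs(same))) if same.size else float(np.mean(np.abs(null)))
        nes = es / denom if denom > 0 else 0.0
        records.append(SetEnrichment(name, int(idx.size), es, float(nes), float(p), 1.0, leading))

    if records:
        adj = bh_adjust([r.p for r in records])
        for r, q in zip(records, adj):
            r.adj_p = float(q)
    return EnrichmentResult(sets=records, skipped=skipped)


# ---------------------------------------------------------------------------
# Per-sample pathway scores (gene-set variation style)
# ---------------------------------------------------------------------------


def _kernel_ecdf(values: np.ndarray, var_floor: float = 1e-8) -> np.ndarray:
    """Gaussian-kernel smoothed ECDF per gene row, bandwidth sd/4."""
    g, n = values.shape
    sd = values.std(axis=1, ddof=1)
    sd = np.sqrt(np.maximum(sd**2, var_floor))
    h = sd / 4.0
    out = np.empty_like(values, dtype=float)
    chunk = max(1, int(2e6 // (n * n)) or 1)
    for start in range(0, g, chunk):
        block = values[start : start + chunk]  # b x n
        diff = (block[:, :, np.newaxis] - block[:, np.newaxis, :]) / h[
            start : start + chunk, np.newaxis, np.newaxis
        ]
        out[start : start + chunk] = norm.cdf(diff).mean(axis=2)
    return out


def sample_scores(
    em: ExpressionMatrix,
    gsc: GeneSetCollection,
    tau: float = 1.0,
    mode: str = "signed_sum",
) -> SampleScoreMatrix:
    """Per-sample, per-gene-set scores from within-sample gene rankings.

    Per gene a kernel ECDF value is computed for every sample; per sample the
    genes are ranked by that value and the symmetric statistic |N/2 - rank|
    weights the same running-sum walk used for GSEA. The default score is
    the signed sum max(walk) + min(walk) ("signed_sum"); "max_magnitude"
    returns the single extremum of larger magnitude instead.
    """
    if len(em.sample_ids) < 2:
        raise DataValidationError("sample scores need at least 2 samples")
    if mode not in {"signed_sum", "max_magnitude"}:
        raise DataValidationError(f"unknown score mode {mode!r}")
    n_genes, n_samples = em.shape
    z = _kernel_ecdf(em.values)

    index = {g: i for i, g in enumerate(em.gene_ids)}
    set_masks: list[tuple[str, np.ndarray]] = []
    for name in gsc.names():
        idx = [index[g] for g in gsc.genes(name) if g in index]
        if not idx or len(idx) >= n_genes:
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        set_masks.append((name, mask))

    scores = np.zeros((len(set_masks), n_samples))
    gene_order_key = np.array(
        sorted(range(n_genes), key=lambda i: em.gene_ids[i]), dtype=int
    )
    # lexicographic tiebreak: pre-rank genes by id, then stable-sort by -z
    tie_rank = np.empty(n_genes, dtype=int)
    tie_rank[gene_order_key] = np.arange(n_genes)
    for j in range(n_samples):
        order = np.lexsort((tie_rank, -z[:, j]))
        zs = z[order, j]
        ranks = np.arange(1, n_genes + 1)  # rank along the descending order
        s = np.abs(n_genes / 2.0 - ranks) ** tau
        # the walk is only evaluated at distinct z levels, so exact ties
        # (e.g. degenerate constant genes) cannot manufacture extrema
        block_end = np.append(zs[:-1] != zs[1:], True)
        for si, (_, mask) in enumerate(set_masks):
            m = mask[order]
            k = int(m.sum())
            nr = float(s[m].sum())
            inc = np.where(m, (s / nr) if nr > 0 else (m / max(k, 1)), -1.0 / (n_genes - k))
            walk = np.cumsum(inc)[block_end]
            if mode == "signed_sum":
                scores[si, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                pos, neg = walk.max(), walk.min()
                scores[si, j] = pos if pos >= -neg else neg
    return SampleScoreMatrix(
        set_names=[name for name, _ in set_masks],
        sample_ids=list(em.sample_ids),
        scores=scores,
    )
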