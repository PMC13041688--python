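"""Gene-set enrichment of the VOE signature and per-sample pathway scores.

Ranks genes by -log10(adjusted p) x log2FC, runs the weighted running-sum
GSEA with random-gene-set permutation nulls against the cohort's gene-set
collection, and computes per-sample (GSVA-style) pathway scores on the
adjusted expression of the longitudinal subjects. Writes results/gsea.tsv
and results/gsva.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from voetx import (
    gsea,
    patient_fold_changes,
    rank_statistic,
    read_expression,
    read_gmt,
    read_metadata,
    sample_scores,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    dge_tbl = pd.read_csv(args.results / "dge.tsv", sep="\t")
    from voetx.dge import DGEResult

    dge = DGEResult(
        gene_ids=dge_tbl["gene_id"].tolist(),
        log2fc=dge_tbl["log2FC"].to_numpy(),
        amean=dge_tbl["A"].to_numpy(),
        t=dge_tbl["t"].to_numpy(),
        df_total=float(dge_tbl["df"].iloc[0]),
        p=dge_tbl["p"].to_numpy(),
        adj_p=dge_tbl["adj_p"].to_numpy(),
    )
    gsc = read_gmt(args.cohort / "gene_sets.gmt")
    rl = rank_statistic(dge)
    enr = gsea(rl, gsc, n_perm=args.perm, seed=args.seed)
    enr.to_frame().to_csv(args.results / "gsea.tsv", sep="\t", index=False)
    sig = enr.significant(0.05)
    print(f"{len(sig)} of {len(enr.sets)} gene sets at BH-adjusted p < 0.05:")
    for s in sig:
        print(f"  {s.name:18s} ES {s.es:+.2f}  NES {s.nes:+.2f}  adj_p {s.adj_p:.3g}")

    # sample-level pathway scores for the longitudinal subjects
    em = read_expression(args.results / "adjusted.tsv")
    meta = read_metadata(args.cohort / "metadata.tsv")
    pfc, _ = patient_fold_changes(em, meta)
    paired_subjects = {p.subject_id for p in pfc}
    keep = [m.sample_id for m in meta if m.subject_id in paired_subjects]
    sm = sample_scores(em.subset_samples(keep), gsc)
    sm.to_frame().to_csv(args.results / "gsva.tsv", sep="\t")
    print(f"per-sample scores for {len(keep)} longitudinal samples written")


if __name__ == "__main__":
    main()
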