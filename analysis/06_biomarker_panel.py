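"""Longitudinal biomarker-panel selection and PC1 scoring.

Selects the genes that are (i) significantly up-regulated during VOE, (ii)
members of a significantly enriched pathway, and (iii) elevated in strictly
more than half of the longitudinal patients; summarises the panel per sample
as PC1 of the standardized panel submatrix; and tests the VOE vs
steady-state score separation with a two-sided pooled t test. Writes
results/biomarker_panel.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from voetx import (
    TimePoint,
    exclude_followup,
    group_difference_test,
    patient_fold_changes,
    pc1_scores,
    read_expression,
    read_gmt,
    read_metadata,
    select_biomarkers,
)
from voetx.dge import DGEResult
from voetx.enrichment import EnrichmentResult, SetEnrichment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    dge_tbl = pd.read_csv(args.results / "dge.tsv", sep="\t")
    dge = DGEResult(
        gene_ids=dge_tbl["gene_id"].tolist(),
        log2fc=dge_tbl["log2FC"].to_numpy(),
        amean=dge_tbl["A"].to_numpy(),
        t=dge_tbl["t"].to_numpy(),
        df_total=float(dge_tbl["df"].iloc[0]),
        p=dge_tbl["p"].to_numpy(),
        adj_p=dge_tbl["adj_p"].to_numpy(),
    )
    gsea_tbl = pd.read_csv(args.results / "gsea.tsv", sep="\t")
    enr = EnrichmentResult(
        sets=[
            SetEnrichment(
                r["set"], int(r["size"]), float(r["ES"]), float(r["NES"]),
                float(r["p"]), float(r["adj_p"]),
                str(r["leading_edge"]).split(";") if r["leading_edge"] else [],
            )
            for _, r in gsea_tbl.iterrows()
        ],
        skipped={},
    )
    gsc = read_gmt(args.cohort / "gene_sets.gmt")
    em = read_expression(args.results / "adjusted.tsv")
    meta = read_metadata(args.cohort / "metadata.tsv")

    pfc, excluded = patient_fold_changes(em, meta)
    panel = select_biomarkers(pfc, dge, enr, gsc)
    print(f"{len(pfc)} longitudinal patients ({len(excluded)} subjects excluded)")
    print(f"panel: {panel.gene_ids}")
    for g in panel.gene_ids:
        print(
            f"  {g}: up in {panel.n_subjects_up[g]}/{panel.n_subjects_eligible} "
            f"patients; pathways: {', '.join(panel.pathway_membership[g])}"
        )

    report = {
        "panel_genes": panel.gene_ids,
        "n_subjects_eligible": panel.n_subjects_eligible,
        "n_subjects_up": panel.n_subjects_up,
        "pathway_membership": panel.pathway_membership,
    }
    if len(panel.gene_ids) >= 2:
        ps = pc1_scores(em, panel.gene_ids)
        active = exclude_followup(meta)
        idx = [ps.sample_ids.index(m.sample_id) for m in active]
        groups = ["voe" if m.time_point is TimePoint.VOE else "ss" for m in active]
        t, p = group_difference_test(ps.scores[idx], groups)
        report.update(
            {
                "pc1_variance_explained": ps.variance_explained,
                "pc1_t": t,
                "pc1_p": p,
            }
        )
        print(f"PC1 variance explained: {ps.variance_explained:.2f}")
        print(f"VOE vs steady-state PC1 t test: t = {t:.2f}, p = {p:.3g}")
    with open(args.results / "biomarker_panel.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
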