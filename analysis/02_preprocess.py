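"""Filter, TMM-normalize, log-transform and covariate-adjust the cohort.

Reads the fixture written by 01_simulate_cohort.py, removes genes with zero
counts in at least 10% of samples, computes TMM factors and log2-CPM, builds
the T-/B-cell axis scores from the marker lists, removes the fixed-effect
nuisance covariates, and writes the normalization factors, the log-CPM
matrix and the adjusted expression matrix under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from voetx import (
    preprocess_cohort,
    read_counts,
    read_gene_list,
    read_metadata,
    write_expression,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cm = read_counts(args.cohort / "counts.tsv")
    meta = read_metadata(args.cohort / "metadata.tsv")
    tcell = read_gene_list(args.cohort / "tcell_markers.txt")
    bcell = read_gene_list(args.cohort / "bcell_markers.txt")

    pre = preprocess_cohort(cm, meta, tcell, bcell)
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": pre.factors.sample_ids,
            "library_size": pre.factors.library_sizes,
            "tmm_factor": pre.factors.tmm_factors,
        }
    ).to_csv(args.out / "tmm_factors.tsv", sep="\t", index=False)
    write_expression(pre.logcpm, args.out / "logcpm.tsv")
    write_expression(pre.adjusted.expression, args.out / "adjusted.tsv")
    with open(args.out / "adjustment.json", "w") as fh:
        json.dump(
            {
                "adjustment_variables": pre.adjusted.adjustment_variables,
                "n_nuisance_dims": pre.adjusted.n_nuisance_dims,
            },
            fh,
            indent=2,
        )

    print(f"{cm.shape[0]} genes -> {pre.filtered.shape[0]} after the 10% zero filter")
    print(f"TMM reference sample: {pre.factors.reference_sample}")
    for ax in pre.axis_scores:
        print(
            f"axis {ax.axis_name}: variance explained "
            f"{ax.variance_explained:.2f} over {len(ax.marker_genes)} markers"
        )
    print(f"adjusted for: {', '.join(pre.adjusted.adjustment_variables)}")


if __name__ == "__main__":
    main()
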