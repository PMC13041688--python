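"""Simulate the synthetic sickle-cell cohort and write it as plain-text files.

Generates the default study conditions — 72 subjects (20 longitudinal with
paired steady-state/VOE samples), negative-binomial counts for 5,000 genes,
five planted VOE-enriched gene sets, four planted biomarker genes, decoys,
and nuisance batch/sex/age/cell-composition structure — and writes counts,
metadata, gene sets, marker lists and the ground truth under
results/cohort/.
"""

import argparse
from pathlib import Path

from voetx import SimulationDesign, write_fixture


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    design = SimulationDesign(rng_seed=args.seed)
    paths = write_fixture(args.out, design)
    print(f"cohort written under {args.out}/ :")
    for key, p in paths.items():
        print(f"  {key:16s} {p}")
    print(
        f"design: {design.n_genes} genes, {design.n_subjects} subjects, "
        f"{len(design.planted_enriched_sets)} enriched sets, "
        f"{design.n_biomarkers} planted biomarkers"
    )


if __name__ == "__main__":
    main()
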