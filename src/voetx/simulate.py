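"""Synthetic sickle-cell cohort generator with ground truth.

Emulates the statistical structure of a paired steady-state / VOE bulk
RNA-seq study: negative-binomial counts with a log-linear mean-dispersion
trend, a shared per-subject random effect that induces within-subject
correlation, planted VOE log2 fold changes concentrated in designated gene
sets, nuisance batch / sex / age effects, a latent two-axis cell-composition
signal carried by small marker-gene modules, a stronger planted enrichment
signal in the chronic-pain stratum, planted biomarker genes constructed to
satisfy the three downstream panel-selection criteria, and decoy genes that
each violate one criterion. A lognormal plasma-protein table emulates the
protein-validation arm.

Everything is deterministic under the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AgeCategory,
    CellFraction,
    CountMatrix,
    DataValidationError,
    GeneSetCollection,
    SampleMetadata,
    Sex,
    TimePoint,
    write_counts,
    write_gene_list,
    write_gmt,
    write_metadata,
)


@dataclass
class SimulationDesign:
    """Parameters of one synthetic cohort.

    Defaults describe a mid-sized paired cohort: 40 subjects of whom half
    are longitudinal (steady state + VOE), a fifth with chronic pain, 200
    planted differentially expressed genes at |log2FC| = 1 with the
    positive shifts concentrated in three enriched 30-gene sets, and a
    1.5x multiplier on planted shifts in the chronic-pain stratum.
    """

    n_genes: int = 5000
    n_subjects: int = 72
    paired_fraction: float = 20.0 / 72.0
    voe_only_fraction_of_unpaired: float = 0.5
    chronic_pain_fraction: float = 0.2
    metformin_fraction: float = 0.1
    followup_subjects: int = 0
    repeat_voe_subjects: int = 0  # paired subjects contributing a 2nd VOE sample

    planted_de_genes: int = 200
    de_log2fc: float = 0.4  # free DE genes outside the enriched sets
    # whether the chronic multiplier also scales the free (out-of-set) DE
    # genes; False models them as generic VOE responses shared by strata
    free_de_multiplied: bool = True
    planted_enriched_sets: tuple[tuple[str, float], ...] = (
        ("SET_ENRICHED_1", 2.4),
        ("SET_ENRICHED_2", 2.4),
        ("SET_ENRICHED_3", 2.4),
        ("SET_ENRICHED_4", 2.4),
        ("SET_ENRICHED_5", 2.4),
    )
    enriched_set_size: int = 100
    enriched_members_shifted: int = 100
    # non-biomarker set members: the set shift applies to VOE samples of
    # VOE-only subjects (cross-sectional elevation); paired subjects respond
    # with member_paired_ratio times the gene's shift. The default (-1/3)
    # makes set-level enrichment decouple from per-patient consistency (only
    # biomarkers respond in everyone); +1 gives fully consistent shifts.
    member_paired_ratio: float = -1.0 / 3.0
    n_null_sets: int = 15
    null_set_size: int = 100
    # "wider" chronic-pain signal: gene sets shifted only in chronic-pain
    # subjects' VOE samples. Their effective shift is
    #   shift * 2 * (chronic_pain_extra_shift - 1),
    # so a shared generative process (multiplier 1) leaves them exactly null
    # and the default 1.5x multiplier activates them at the stated shift.
    chronic_only_sets: tuple[tuple[str, float], ...] = ()
    chronic_only_set_size: int = 100
    chronic_pain_extra_shift: float = 1.5

    n_biomarkers: int = 4
    biomarker_log2fc: float = 1.0
    plant_decoys: bool = True

    # weak polygenic background outside gene sets / markers / planted genes:
    # gives the ranking statistic the smooth decay seen in real cohorts
    background_gene_fraction: float = 0.30
    background_effect_sd: float = 0.20

    batch_effect: float = 0.5
    batch_gene_fraction: float = 0.10
    sex_effect: float = 0.5
    sex_gene_fraction: float = 0.02
    age_effect: float = 0.3
    age_gene_fraction: float = 0.05
    cell_composition_effect: float = 1.0
    composition_gene_fraction: float = 0.10
    composition_bystander_effect: float = 0.3

    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    nb_dispersion_intercept: float = -1.5  # phi = exp(a + b * ln(mu))
    nb_dispersion_slope: float = -0.3
    subject_effect_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_subjects <= 0:
            raise DataValidationError("n_genes and n_subjects must be positive")
        for name in ("paired_fraction", "chronic_pain_fraction", "metformin_fraction",
                     "voe_only_fraction_of_unpaired"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataValidationError(f"{name} must be in [0, 1]")
        if self.planted_de_genes > self.n_genes:
            raise DataValidationError("planted_de_genes cannot exceed n_genes")
        if self.enriched_members_shifted > self.enriched_set_size:
            raise DataValidationError(
                "enriched_members_shifted cannot exceed enriched_set_size"
            )
        needed = (
            20  # marker modules
            + len(self.planted_enriched_sets) * self.enriched_set_size
            + len(self.chronic_only_sets) * self.chronic_only_set_size
            + self.n_null_sets * self.null_set_size
            + self.planted_de_genes
        )
        if needed > self.n_genes:
            raise DataValidationError(
                f"design infeasible: {needed} reserved genes exceed n_genes={self.n_genes}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    de_log2fc: dict[str, float]  # population-average VOE effect per DE gene
    background_log2fc: dict[str, float]  # weak polygenic background effects
    chronic_only_log2fc: dict[str, float]  # VOE effects present only in chronic subjects
    enriched_set_names: list[str]
    chronic_only_set_names: list[str]
    biomarker_gene_ids: list[str]
    decoy_gene_ids: dict[str, str]  # gene id -> which criterion it violates
    tcell_markers: list[str]
    bcell_markers: list[str]
    gene_sets: GeneSetCollection
    sample_nuisance: pd.DataFrame  # per-sample batch / latent composition fractions

    @property
    def de_gene_ids(self) -> list[str]:
        return list(self.de_log2fc.keys())


def comparison_design(
    seed: int, chronic_multiplier: float = 1.5, n_genes: int = 3000
) -> SimulationDesign:
    """Reduced cohort for the bootstrap stratum comparison.

    Same architecture as the default design at a smaller problem size
    (3,000 genes, 60-gene sets), so the full chain can be recomputed for
    every bootstrap subset at reasonable cost. ``chronic_multiplier`` = 1
    gives a shared generative process across strata (the calibration null);
    1.5 plants the stronger and wider chronic-pain enrichment signal: shared
    set shifts are amplified and the chronic-only sets switch on (their
    shift scales with multiplier - 1, so they are exactly null at 1).
    """
    # a ladder of shared set strengths, chronic-only sets carrying the
    # "wider" stratum signal, and strong out-of-set DE genes giving the
    # ranking statistic a realistic heavy top
    ladder = (0.84, 0.73, 0.62, 0.50, 0.39, 0.28)
    return SimulationDesign(
        n_genes=n_genes,
        planted_de_genes=560,
        de_log2fc=1.0,
        planted_enriched_sets=tuple(
            (f"SET_ENRICHED_{i + 1}", s) for i, s in enumerate(ladder)
        ),
        enriched_set_size=60,
        enriched_members_shifted=60,
        n_null_sets=6,
        null_set_size=60,
        chronic_only_sets=tuple(
            (f"SET_CHRONIC_{i + 1}", s) for i, s in enumerate((1.2, 1.1, 1.0, 0.9))
        ),
        chronic_only_set_size=60,
        member_paired_ratio=1.0,  # consistent within-patient pathway response
        chronic_pain_extra_shift=chronic_multiplier,
        chronic_pain_fraction=0.35,
        background_gene_fraction=0.2,
        background_effect_sd=0.15,
        rng_seed=seed,
    )


def _assign_samples(design: SimulationDesign, rng: np.random.Generator):
    """Per-subject attributes and the sample table (subject, time point)."""
    n = design.n_subjects
    n_paired = int(round(design.paired_fraction * n))
    unpaired = n - n_paired
    n_voe_only = int(round(design.voe_only_fraction_of_unpaired * unpaired))
    roles = (["paired"] * n_paired + ["voe_only"] * n_voe_only
             + ["ss_only"] * (unpaired - n_voe_only))

    subjects = []
    for i in range(n):
        subjects.append(
            {
                "subject_id": f"P{i:03d}",
                "role": roles[i],
                "chronic_pain": bool(rng.random() < design.chronic_pain_fraction),
                "metformin": bool(rng.random() < design.metformin_fraction),
                "sex": Sex.F if rng.random() < 0.5 else Sex.M,
                "age_category": [AgeCategory.UNDER10, AgeCategory.TEN_TO_18,
                                 AgeCategory.OVER18][int(rng.integers(3))],
            }
        )

    samples = []  # (subject index, time point)
    repeat_left = design.repeat_voe_subjects
    follow_left = design.followup_subjects
    for i, subj in enumerate(subjects):
        if subj["role"] in ("paired", "ss_only"):
            samples.append((i, TimePoint.STEADY_STATE))
        if subj["role"] in ("paired", "voe_only"):
            samples.append((i, TimePoint.VOE))
            if subj["role"] == "paired" and repeat_left > 0:
                samples.append((i, TimePoint.VOE))
                repeat_left -= 1
        if subj["role"] == "paired" and follow_left > 0:
            samples.append((i, TimePoint.FOLLOWUP))
            follow_left -= 1
    return subjects, samples


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[CountMatrix, list[SampleMetadata], SyntheticTruth]:
    """Draw one cohort: NB counts, sample metadata and ground truth."""
    rng = np.random.default_rng(design.rng_seed)
    g = design.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]

    # --- reserve gene roles -------------------------------------------------
    cursor = 0
    tcell = gene_ids[cursor : cursor + 10]
    cursor += 10
    bcell = gene_ids[cursor : cursor + 10]
    cursor += 10

    set_names = [name for name, _ in design.planted_enriched_sets]
    set_shifts = {name: s for name, s in design.planted_enriched_sets}
    enriched_members: dict[str, list[str]] = {}
    shifted_set_genes: list[str] = []
    for name in set_names:
        members = gene_ids[cursor : cursor + design.enriched_set_size]
        cursor += design.enriched_set_size
        enriched_members[name] = members
        shifted_set_genes.extend(members[: design.enriched_members_shifted])

    chronic_members: dict[str, list[str]] = {}
    chronic_lfc: dict[str, float] = {}
    chronic_gain = 2.0 * (design.chronic_pain_extra_shift - 1.0)
    for name, shift in design.chronic_only_sets:
        members = gene_ids[cursor : cursor + design.chronic_only_set_size]
        cursor += design.chronic_only_set_size
        chronic_members[name] = members
        eff = shift * chronic_gain
        for m in members:
            chronic_lfc[m] = float(max(0.0, rng.normal(eff, 0.2 * abs(eff)))) if eff > 0 else 0.0

    null_sets: dict[str, list[str]] = {}
    for i in range(design.n_null_sets):
        members = gene_ids[cursor : cursor + design.null_set_size]
        cursor += design.null_set_size
        null_sets[f"SET_NULL_{i + 1}"] = members

    # biomarkers: first genes of each enriched set, strongly and uniformly up
    biomarkers: list[str] = []
    for i in range(design.n_biomarkers):
        name = set_names[i % len(set_names)] if set_names else None
        if name is None:
            break
        pool = [m for m in enriched_members[name] if m not in biomarkers]
        biomarkers.append(pool[i // len(set_names)])

    lfc: dict[str, float] = {}  # consistent within-patient VOE response
    member_lfc: dict[str, float] = {}  # cross-sectional elevation (VOE-only subjects)
    for name in set_names:
        shift = set_shifts[name]
        for m in enriched_members[name][: design.enriched_members_shifted]:
            member_lfc[m] = float(max(0.1, rng.normal(shift, 0.2 * abs(shift))))
    for b in biomarkers:
        member_lfc.pop(b, None)
        lfc[b] = design.biomarker_log2fc

    n_free = design.planted_de_genes - len(lfc) - len(member_lfc)
    free_de = gene_ids[cursor : cursor + max(0, n_free)]
    cursor += max(0, n_free)
    for i, gid in enumerate(free_de):
        lfc[gid] = design.de_log2fc if i % 2 == 0 else -design.de_log2fc

    decoys: dict[str, str] = {}
    decoy_hetero: dict[str, tuple[float, float]] = {}  # unpaired-voe, paired-voe shifts
    if design.plant_decoys and design.planted_de_genes > 0:
        d1, d2, d3 = gene_ids[cursor : cursor + 3]
        cursor += 3
        decoys[d1] = "not_in_significant_pathway"
        lfc[d1] = 1.5  # strong, consistent, but in no gene set
        decoys[d2] = "not_differentially_expressed"
        if set_names:  # null gene planted inside an enriched set
            enriched_members[set_names[0]] = enriched_members[set_names[0]][:-1] + [d2]
        decoys[d3] = "not_up_in_majority_of_patients"
        if set_names:
            enriched_members[set_names[-1]] = enriched_members[set_names[-1]][:-2] + [
                d3,
                enriched_members[set_names[-1]][-1],
            ]
        decoy_hetero[d3] = (2.5, -1.0)
        lfc[d3] = 0.0  # recorded below from the realized mix

    gsc = GeneSetCollection(
        {
            **{name: (f"planted enriched set ({set_shifts[name]:+.2f})", enriched_members[name])
               for name in set_names},
            **{name: ("chronic-pain-only set", members)
               for name, members in chronic_members.items()},
            **{name: ("null set", members) for name, members in null_sets.items()},
        }
    ) if (set_names or null_sets or chronic_members) else GeneSetCollection(
        {"SET_DUMMY": ("placeholder", gene_ids[:5])}
    )

    # --- subjects and samples ----------------------------------------------
    subjects, sample_plan = _assign_samples(design, rng)
    n_samples = len(sample_plan)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    base = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, size=g)
    subj_z = rng.normal(0.0, 1.0, size=(design.n_subjects, g))
    # axis markers, pathway members and biomarkers are abundant transcripts in
    # real blood (immune/inflammation genes); keep them clear of the
    # zero-count filter and of the high-dispersion low-count regime
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for gid in (*tcell, *bcell):
        base[gene_pos[gid]] = max(base[gene_pos[gid]], design.baseline_log2_mean + 2.0)
    for gid in (*member_lfc, *chronic_lfc, *biomarkers):
        base[gene_pos[gid]] = max(base[gene_pos[gid]], design.baseline_log2_mean + 1.5)
    # subject random effect scaled to each gene's measurement noise, so the
    # within-subject correlation is (approximately) shared across genes, as
    # the exchangeable-correlation DGE model assumes
    mu_base = np.exp2(base)
    phi_base = np.exp(
        design.nb_dispersion_intercept + design.nb_dispersion_slope * np.log(mu_base)
    )
    sigma_gene = np.sqrt(1.0 / mu_base + phi_base) / np.log(2.0)
    mu_ref = 2.0**design.baseline_log2_mean
    phi_ref = np.exp(
        design.nb_dispersion_intercept + design.nb_dispersion_slope * np.log(mu_ref)
    )
    sigma_ref = np.sqrt(1.0 / mu_ref + phi_ref) / np.log(2.0)
    subj_eff = subj_z * (design.subject_effect_sd / sigma_ref) * sigma_gene

    def pick(frac: float, exclude: set[str]) -> np.ndarray:
        pool = np.array([i for i, gid in enumerate(gene_ids) if gid not in exclude])
        n_pick = int(round(frac * g))
        return rng.choice(pool, size=min(n_pick, pool.size), replace=False)

    in_any_set: set[str] = set()
    for members in enriched_members.values():
        in_any_set.update(members)
    for members in chronic_members.values():
        in_any_set.update(members)
    for members in null_sets.values():
        in_any_set.update(members)
    background_lfc: dict[str, float] = {}
    if design.background_effect_sd > 0 and design.background_gene_fraction > 0:
        bg_excl = (set(tcell) | set(bcell) | set(lfc) | set(member_lfc)
                   | set(decoys) | in_any_set)
        bg_pool = [gid for gid in gene_ids if gid not in bg_excl]
        n_bg = min(int(round(design.background_gene_fraction * g)), len(bg_pool))
        bg_idx = rng.choice(len(bg_pool), size=n_bg, replace=False)
        for i in bg_idx:
            background_lfc[bg_pool[int(i)]] = float(
                rng.normal(0.0, design.background_effect_sd)
            )

    protected = (set(tcell) | set(bcell) | set(lfc) | set(member_lfc) | set(decoys)
                 | set(chronic_lfc) | set(background_lfc))
    batch_genes = pick(design.batch_gene_fraction, protected)
    sex_genes = pick(design.sex_gene_fraction, protected)
    age_genes = pick(design.age_gene_fraction, protected)
    comp_genes = pick(design.composition_gene_fraction, protected)

    batch_vec = np.zeros(g)
    batch_vec[batch_genes] = design.batch_effect
    sex_vec = np.zeros(g)
    sex_vec[sex_genes] = design.sex_effect
    age_vec = np.zeros(g)
    age_vec[age_genes] = design.age_effect

    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    t_load = np.zeros(g)
    b_load = np.zeros(g)
    for gid in tcell:
        t_load[gene_index[gid]] = design.cell_composition_effect
    for gid in bcell:
        b_load[gene_index[gid]] = design.cell_composition_effect
    half = len(comp_genes) // 2
    t_load[comp_genes[:half]] = design.composition_bystander_effect
    b_load[comp_genes[half:]] = design.composition_bystander_effect

    voe_vec = np.zeros(g)
    voe_shared_vec = np.zeros(g)
    for gid, v in lfc.items():
        if design.free_de_multiplied or gid in biomarkers:
            voe_vec[gene_index[gid]] = v
        else:
            voe_shared_vec[gene_index[gid]] = v
    member_unpaired_vec = np.zeros(g)
    member_paired_vec = np.zeros(g)
    for gid, v in member_lfc.items():
        member_unpaired_vec[gene_index[gid]] = v
        member_paired_vec[gene_index[gid]] = design.member_paired_ratio * v
    bg_vec = np.zeros(g)
    for gid, v in background_lfc.items():
        bg_vec[gene_index[gid]] = v
    chronic_vec = np.zeros(g)
    for gid, v in chronic_lfc.items():
        chronic_vec[gene_index[gid]] = v

    meta: list[SampleMetadata] = []
    nuisance_rows = []
    log2mu = np.empty((g, n_samples))
    for j, (si, tp) in enumerate(sample_plan):
        subj = subjects[si]
        batch = "B1" if rng.random() < 0.5 else "B2"
        t_frac = float(rng.normal(0.0, 1.0))
        b_frac = float(rng.normal(0.0, 1.0))
        mu = base + subj_eff[si]
        if batch == "B2":
            mu = mu + batch_vec
        if subj["sex"] is Sex.F:
            mu = mu + sex_vec
        age_code = [AgeCategory.UNDER10, AgeCategory.TEN_TO_18, AgeCategory.OVER18].index(
            subj["age_category"]
        )
        mu = mu + age_vec * age_code
        mu = mu + t_load * t_frac + b_load * b_frac
        if tp is TimePoint.VOE:
            mult = design.chronic_pain_extra_shift if subj["chronic_pain"] else 1.0
            mu = mu + voe_vec * mult + voe_shared_vec + bg_vec
            member_vec = member_paired_vec if subj["role"] == "paired" else member_unpaired_vec
            mu = mu + member_vec * mult
            if subj["chronic_pain"]:
                mu = mu + chronic_vec  # amplitude already encodes the multiplier
            for gid, (up_unpaired, up_paired) in decoy_hetero.items():
                shift = up_paired if subj["role"] == "paired" else up_unpaired
                mu[gene_index[gid]] += shift * mult
        elif tp is TimePoint.FOLLOWUP:
            # partial reversion toward baseline
            mu = mu + 0.3 * (voe_vec + voe_shared_vec)
        log2mu[:, j] = mu
        meta.append(
            SampleMetadata(
                sample_id=sample_ids[j],
                subject_id=subj["subject_id"],
                time_point=tp,
                chronic_pain=subj["chronic_pain"],
                sex=subj["sex"],
                age_category=subj["age_category"],
                batch=batch,
                metformin=subj["metformin"],
                cell_fraction=CellFraction.CD45,
            )
        )
        nuisance_rows.append(
            {
                "sample_id": sample_ids[j],
                "batch": batch,
                "tcell_fraction": t_frac,
                "bcell_fraction": b_frac,
            }
        )

    mu = np.exp2(log2mu)
    phi = np.exp(design.nb_dispersion_intercept + design.nb_dispersion_slope * np.log(mu))
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64))

    # record realized population-average effects of the heterogeneous genes
    n_vp = sum(1 for si, tp in sample_plan
               if tp is TimePoint.VOE and subjects[si]["role"] == "paired")
    n_vu = sum(1 for si, tp in sample_plan
               if tp is TimePoint.VOE and subjects[si]["role"] != "paired")
    tot = max(n_vp + n_vu, 1)
    for gid, v in member_lfc.items():
        lfc[gid] = (n_vp * design.member_paired_ratio * v + n_vu * v) / tot
    for gid, (up_unpaired, up_paired) in decoy_hetero.items():
        lfc[gid] = (n_vp * up_paired + n_vu * up_unpaired) / tot

    truth = SyntheticTruth(
        de_log2fc=lfc,
        background_log2fc=background_lfc,
        chronic_only_log2fc=chronic_lfc,
        enriched_set_names=list(set_names),
        chronic_only_set_names=list(chronic_members.keys()),
        biomarker_gene_ids=biomarkers,
        decoy_gene_ids=decoys,
        tcell_markers=tcell,
        bcell_markers=bcell,
        gene_sets=gsc,
        sample_nuisance=pd.DataFrame(nuisance_rows),
    )
    return cm, meta, truth


def simulate_plasma_panel(
    n_ss: int,
    n_voe: int,
    shift: float,
    seed: int = 0,
    analytes: Sequence[str] = ("IL1B", "MS4A4A", "SERPINB2", "FAM20A"),
    shifted_analytes: Sequence[str] = ("IL1B",),
) -> pd.DataFrame:
    """Lognormal plasma analyte table with a VOE-group shift on chosen analytes.

    Values are 2**N(3, 1); VOE samples of each designated analyte are
    multiplied by 2**shift.
    """
    if n_ss < 2 or n_voe < 2:
        raise DataValidationError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    groups = ["steady_state"] * n_ss + ["voe"] * n_voe
    data: dict[str, list] = {
        "sample_id": [f"PL{i:03d}" for i in range(n_ss + n_voe)],
        "group": groups,
    }
    for a in analytes:
        log2v = rng.normal(3.0, 1.0, size=n_ss + n_voe)
        if a in shifted_analytes:
            log2v[n_ss:] += shift
        data[a] = list(np.exp2(log2v))
    return pd.DataFrame(data)


def write_fixture(dir_path: str | Path, design: SimulationDesign) -> dict[str, Path]:
    """Simulate a cohort and write it as re-readable plain-text files."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise DataValidationError(f"{out} is not a writable directory")
    cm, meta, truth = simulate_cohort(design)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "tcell_markers": out / "tcell_markers.txt",
        "bcell_markers": out / "bcell_markers.txt",
        "truth": out / "truth.yaml",
    }
    write_counts(cm, paths["counts"])
    write_metadata(meta, paths["metadata"])
    write_gmt(truth.gene_sets, paths["gene_sets"])
    write_gene_list(truth.tcell_markers, paths["tcell_markers"])
    write_gene_list(truth.bcell_markers, paths["bcell_markers"])
    truth_doc = {
        "de_log2fc": {k: float(v) for k, v in truth.de_log2fc.items()},
        "enriched_set_names": truth.enriched_set_names,
        "biomarker_gene_ids": truth.biomarker_gene_ids,
        "decoy_gene_ids": truth.decoy_gene_ids,
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    return paths
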