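"""Core data containers, file IO and validation shared by every pipeline stage.

The pipeline operates on three on-disk formats: tab-separated count and
expression matrices (first column ``gene_id``, remaining columns samples),
a tab-separated sample-metadata table, and GMT gene-set files. All readers
validate on load and raise :class:`DataValidationError` with coordinates on
malformed input; nothing is imputed or silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class DataValidationError(ValueError):
    """Raised when an input file or constructed container violates an invariant."""


class TimePoint(str, enum.Enum):
    STEADY_STATE = "steady_state"
    VOE = "voe"
    FOLLOWUP = "followup"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class AgeCategory(str, enum.Enum):
    """Age bins: below 10 years, 10-18 years, above 18 years."""

    UNDER10 = "under10"
    TEN_TO_18 = "ten_to_18"
    OVER18 = "over18"


class CellFraction(str, enum.Enum):
    CD45 = "CD45"
    CD71 = "CD71"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise DataValidationError("need at least 1 gene and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise DataValidationError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise DataValidationError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(np.float64)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of finite log2-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite expression at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class SampleMetadata:
    """Design and covariate record for one sequenced sample."""

    sample_id: str
    subject_id: str
    time_point: TimePoint
    chronic_pain: bool
    sex: Sex
    age_category: AgeCategory
    batch: str
    metformin: bool
    cell_fraction: CellFraction
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the MSigDB Hallmark collection) in load order."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise DataValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # dedup preserving order; duplicates are legal in GMT files
                seen: set[str] = set()
                deduped = [g for g in genes if not (g in seen or seen.add(g))]
                self.sets[name] = (self.sets[name][0], deduped)

    def names(self) -> list[str]:
        return list(self.sets.keys())

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PipelineConfig:
    """Tunable constants for the whole pipeline.

    Defaults mirror the study's stated analysis choices: genes with zeros in
    at least 10% of samples are removed, BH-adjusted p < 0.05 declares
    significance, and the stratum comparison draws 30 bootstrap subsets.
    """

    filter_zero_fraction: float = 0.10
    fdr_threshold: float = 0.05
    gsea_permutations: int = 1000
    bootstrap_subsets: int = 30
    rng_seed: int = 0
    log_base_for_rank: int = 10  # fixed convention for the ranking statistic
    gsea_weight_exponent: float = 1.0
    marker_gene_lists: dict[str, str] = field(default_factory=dict)
    biomarker_majority: str = "strict"

    def __post_init__(self) -> None:
        if not (0.0 < self.filter_zero_fraction <= 1.0):
            raise DataValidationError("filter_zero_fraction must be in (0, 1]")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise DataValidationError("fdr_threshold must be in (0, 1)")
        if self.gsea_permutations < 100:
            raise DataValidationError("gsea_permutations must be >= 100")
        if self.bootstrap_subsets <= 0:
            raise DataValidationError("bootstrap_subsets must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

GENE_ID_COLUMN = "gene_id"

_REQUIRED_META_COLUMNS = [
    "sample_id",
    "subject_id",
    "time_point",
    "chronic_pain",
    "sex",
    "age_category",
    "batch",
    "metformin",
    "cell_fraction",
]


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated gene x sample integer count matrix.

    The first column must be headed ``gene_id``; every other column is a
    sample. Errors carry the offending gene/sample coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != GENE_ID_COLUMN:
        raise DataValidationError(
            f"first column must be {GENE_ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    gene_ids = df[GENE_ID_COLUMN].tolist()
    sample_ids = list(df.columns[1:])
    body = df.iloc[:, 1:]
    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        col = body.iloc[:, j]
        for i, raw in enumerate(col):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise DataValidationError(
                    f"non-integer count {raw!r} at gene {gene_ids[i]!r} (row {i + 2}), "
                    f"sample {s!r}"
                ) from None
            if v < 0:
                raise DataValidationError(
                    f"negative count {v} at gene {gene_ids[i]!r} (row {i + 2}), sample {s!r}"
                )
            counts[i, j] = v
    return CountMatrix(gene_ids, sample_ids, counts)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, GENE_ID_COLUMN, cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != GENE_ID_COLUMN:
        raise DataValidationError(
            f"first column must be {GENE_ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    gene_ids = df[GENE_ID_COLUMN].astype(str).tolist()
    sample_ids = list(df.columns[1:])
    return ExpressionMatrix(gene_ids, sample_ids, df.iloc[:, 1:].to_numpy(dtype=np.float64))


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, columns=em.sample_ids)
    df.insert(0, GENE_ID_COLUMN, em.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"GMT line {lineno} has {len(fields)} fields; need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise DataValidationError(f"duplicate gene set name {name!r} at line {lineno}")
            seen: set[str] = set()
            genes = [g for g in fields[2:] if g and not (g in seen or seen.add(g))]
            if not genes:
                raise DataValidationError(f"gene set {name!r} at line {lineno} is empty")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in gsc.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _parse_bool(raw: str, column: str, row: int) -> bool:
    low = str(raw).strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise DataValidationError(f"invalid boolean {raw!r} in column {column!r}, row {row}")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata table; enum and boolean columns are validated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"metadata is missing required column(s): {missing}")
    extra_cols = [c for c in df.columns if c not in _REQUIRED_META_COLUMNS]
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, counting the header line
        if row.isna().any():
            bad = row.index[row.isna()][0]
            raise DataValidationError(f"missing value in column {bad!r}, row {rowno}")
        sid = str(row["sample_id"])
        if sid in seen:
            raise DataValidationError(f"duplicate sample_id {sid!r} at row {rowno}")
        seen.add(sid)
        try:
            tp = TimePoint(row["time_point"])
            sex = Sex(row["sex"])
            age = AgeCategory(row["age_category"])
            frac = CellFraction(row["cell_fraction"])
        except ValueError as exc:
            raise DataValidationError(f"invalid enum value at row {rowno}: {exc}") from None
        records.append(
            SampleMetadata(
                sample_id=sid,
                subject_id=str(row["subject_id"]),
                time_point=tp,
                chronic_pain=_parse_bool(row["chronic_pain"], "chronic_pain", rowno),
                sex=sex,
                age_category=age,
                batch=str(row["batch"]),
                metformin=_parse_bool(row["metformin"], "metformin", rowno),
                cell_fraction=frac,
                extra={c: str(row[c]) for c in extra_cols},
            )
        )
    return records


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "sample_id": m.sample_id,
                "subject_id": m.subject_id,
                "time_point": m.time_point.value,
                "chronic_pain": str(m.chronic_pain).lower(),
                "sex": m.sex.value,
                "age_category": m.age_category.value,
                "batch": m.batch,
                "metformin": str(m.metformin).lower(),
                "cell_fraction": m.cell_fraction.value,
                **m.extra,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def check_sample_join(cm: CountMatrix, meta: Sequence[SampleMetadata]) -> dict[str, list[str]]:
    """Cross-check count-matrix samples against metadata; returns orphan lists."""
    meta_ids = {m.sample_id for m in meta}
    cm_ids = set(cm.sample_ids)
    return {
        "counts_without_metadata": sorted(cm_ids - meta_ids),
        "metadata_without_counts": sorted(meta_ids - cm_ids),
    }


def metadata_by_sample(meta: Sequence[SampleMetadata]) -> Mapping[str, SampleMetadata]:
    return {m.sample_id: m for m in meta}


def read_gene_list(path: str | Path) -> list[str]:
    """One-gene-per-line plain-text marker list (blank lines ignored)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    _check_unique(genes, "marker gene")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def exclude_followup(
    meta: Sequence[SampleMetadata], include_followup: bool = False
) -> list[SampleMetadata]:
    """Drop follow-up samples unless explicitly re-included.

    Follow-up visits are accepted by the readers but excluded from the
    differential-expression and enrichment stages by default; the flag exists
    for descriptive fold-change reporting only.
    """
    if include_followup:
        return list(meta)
    return [m for m in meta if m.time_point is not TimePoint.FOLLOWUP]
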