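import numpy as np
import pytest

from voetx import (
    AgeCategory,
    CellFraction,
    CountMatrix,
    ExpressionMatrix,
    SampleMetadata,
    Sex,
    SimulationDesign,
    TimePoint,
    simulate_cohort,
)


def make_meta(
    sample_id,
    subject_id,
    time_point="steady_state",
    chronic_pain=False,
    sex="M",
    age="over18",
    batch="B1",
    metformin=False,
):
    return SampleMetadata(
        sample_id=sample_id,
        subject_id=subject_id,
        time_point=TimePoint(time_point),
        chronic_pain=chronic_pain,
        sex=Sex(sex),
        age_category=AgeCategory(age),
        batch=batch,
        metformin=metformin,
        cell_fraction=CellFraction.CD45,
    )


@pytest.fixture
def paired_meta():
    """10 subjects, each with one steady-state and one VOE sample."""
    meta = []
    for i in range(10):
        meta.append(make_meta(f"S{i:02d}a", f"P{i}", "steady_state", batch="B1" if i % 2 else "B2"))
        meta.append(make_meta(f"S{i:02d}b", f"P{i}", "voe", batch="B1" if i % 2 else "B2"))
    return meta


@pytest.fixture
def paired_expression(paired_meta):
    """Gaussian expression for the paired cohort, no planted effects."""
    rng = np.random.default_rng(11)
    sids = [m.sample_id for m in paired_meta]
    vals = rng.normal(8.0, 1.0, size=(50, len(sids)))
    return ExpressionMatrix([f"g{i:03d}" for i in range(50)], sids, vals)


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(5, 0.05, size=(40, 6))
    return CountMatrix(
        [f"g{i:02d}" for i in range(40)], [f"s{j}" for j in range(6)], counts
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by read-only tests."""
    design = SimulationDesign(
        n_genes=800,
        n_subjects=24,
        paired_fraction=0.5,
        planted_de_genes=60,
        planted_enriched_sets=(("SET_ENRICHED_1", 2.4),),
        enriched_set_size=30,
        enriched_members_shifted=30,
        n_null_sets=3,
        null_set_size=30,
        n_biomarkers=2,
        rng_seed=42,
    )
    return simulate_cohort(design)
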