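"""Filtering, TMM normalization, log-CPM and sex verification."""

import numpy as np
import pytest

from voetx import (
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    filter_low_expression,
    log_cpm,
    tmm_factors,
    verify_sex,
)
from .conftest import make_meta


def tmm_oracle(counts, ref_idx, logratio_trim=0.30, abs_trim=0.05):
    """Line-by-line reference implementation of the TMM factor formulas."""
    lib = counts.sum(axis=0).astype(float)
    n = counts.shape[1]
    factors = np.ones(n)
    y_r, n_r = counts[:, ref_idx].astype(float), lib[ref_idx]
    for k in range(n):
        if k == ref_idx:
            continue
        y_k, n_k = counts[:, k].astype(float), lib[k]
        pos = (y_k > 0) & (y_r > 0)
        yk, yr = y_k[pos], y_r[pos]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        keep = np.ones(len(m), dtype=bool)
        lo, hi = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        keep &= (m >= lo) & (m <= hi)
        lo, hi = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep &= (a >= lo) & (a <= hi)
        w = 1.0 / ((n_k - yk[keep]) / (n_k * yk[keep]) + (n_r - yr[keep]) / (n_r * yr[keep]))
        factors[k] = 2 ** (np.sum(w * m[keep]) / np.sum(w))
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilter:
    def test_at_least_ten_percent_zero_rule(self):
        # 20 samples: zeros in 2 samples (10%) -> removed; 1 sample (5%) -> kept
        counts = np.full((3, 20), 5, dtype=int)
        counts[0, :2] = 0  # 10% zeros: removed
        counts[1, 0] = 0  # 5% zeros: retained
        cm = CountMatrix(["gA", "gB", "gC"], [f"s{i}" for i in range(20)], counts)
        kept = filter_low_expression(cm, 0.10)
        assert kept.gene_ids == ["gB", "gC"]

    def test_idempotent(self, small_counts):
        once = filter_low_expression(small_counts, 0.2)
        twice = filter_low_expression(once, 0.2)
        assert twice.gene_ids == once.gene_ids

    def test_matches_brute_force_survivors(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(1, 0.2, size=(500, 30))
        cm = CountMatrix([f"g{i}" for i in range(500)], [f"s{j}" for j in range(30)], counts)
        kept = filter_low_expression(cm, 0.10)
        expected = [
            f"g{i}"
            for i in range(500)
            if sum(counts[i, j] == 0 for j in range(30)) / 30 < 0.10
        ]
        assert kept.gene_ids == expected

    def test_all_removed_is_error(self):
        cm = CountMatrix(["g"] , ["a", "b"], np.array([[0, 1]]))
        with pytest.raises(DataValidationError, match="every gene"):
            filter_low_expression(cm, 0.10)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        cm = CountMatrix(
            [f"g{i}" for i in range(100)],
            ["a", "b", "c"],
            np.column_stack([col, col, col]),
        )
        nf = tmm_factors(cm)
        assert np.allclose(nf.tmm_factors, 1.0, atol=1e-12)

    def test_pure_library_size_scaling_gives_unit_factors(self):
        col = np.arange(1, 101)
        cm = CountMatrix(
            [f"g{i}" for i in range(100)], ["a", "b"], np.column_stack([col, 2 * col])
        )
        nf = tmm_factors(cm)
        assert np.allclose(nf.tmm_factors, 1.0, atol=1e-9)

    def test_matches_formula_oracle_under_composition_bias(self):
        rng = np.random.default_rng(9)
        counts = rng.negative_binomial(10, 0.05, size=(200, 4)) + 1
        counts[:20, 0] *= 8  # composition spike in one sample
        cm = CountMatrix(
            [f"g{i}" for i in range(200)], [f"s{j}" for j in range(4)], counts
        )
        nf = tmm_factors(cm)
        ref_idx = cm.sample_ids.index(nf.reference_sample)
        expected = tmm_oracle(counts, ref_idx)
        assert np.allclose(nf.tmm_factors, expected, atol=1e-10)

    def test_invariant_to_gene_order(self, small_counts):
        nf = tmm_factors(small_counts)
        perm = np.random.default_rng(1).permutation(len(small_counts.gene_ids))
        shuffled = CountMatrix(
            [small_counts.gene_ids[i] for i in perm],
            list(small_counts.sample_ids),
            small_counts.counts[perm],
        )
        nf2 = tmm_factors(shuffled)
        assert np.allclose(nf.tmm_factors, nf2.tmm_factors, atol=1e-12)

    def test_geometric_mean_is_one(self, small_counts):
        nf = tmm_factors(small_counts)
        assert abs(np.exp(np.mean(np.log(nf.tmm_factors))) - 1.0) < 1e-12


class TestLogCPM:
    def test_zero_count_formula_value(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(100, 2000, size=(80, 2))
        counts[0] = 0  # a silent gene
        cm = CountMatrix([f"g{i}" for i in range(80)], ["a", "b"], counts)
        nf = tmm_factors(cm)
        em = log_cpm(cm, nf, prior_count=0.5)
        lib = nf.effective_library_sizes[0]
        expected = np.log2(0.5 / (lib + 1.0) * 1e6)
        assert em.values[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_count_within_sample(self, small_counts):
        nf = tmm_factors(small_counts)
        em = log_cpm(small_counts, nf)
        j = 0
        order = np.argsort(small_counts.counts[:, j])
        assert np.all(np.diff(em.values[order, j]) >= 0)

    def test_doubling_counts_and_library_is_stable(self):
        # the prior-count perturbation shrinks ~1/count; use well-covered genes
        rng = np.random.default_rng(2)
        counts = rng.integers(1000, 5000, size=(300, 3))
        cm1 = CountMatrix([f"g{i}" for i in range(300)], ["a", "b", "c"], counts)
        cm2 = CountMatrix([f"g{i}" for i in range(300)], ["a", "b", "c"], counts * 2)
        em1 = log_cpm(cm1, tmm_factors(cm1))
        em2 = log_cpm(cm2, tmm_factors(cm2))
        assert np.max(np.abs(em1.values - em2.values)) < 1e-3


class TestVerifySex:
    def _em(self, xist, rps4y1):
        vals = np.array([[xist], [rps4y1], [5.0]])
        return ExpressionMatrix(["XIST", "RPS4Y1", "other"], ["s1"], np.repeat(vals, 2, axis=1))

    def test_concordant_female(self):
        em = ExpressionMatrix(["XIST", "RPS4Y1"], ["s1", "s2"], np.array([[8.0, 8.0], [0.0, 0.0]]))
        meta = [make_meta("s1", "P1", sex="F"), make_meta("s2", "P2", sex="M")]
        report = verify_sex(em, meta)
        assert report[0].concordant is True
        assert report[1].concordant is False  # recorded M, markers say F

    def test_missing_marker_is_error(self, paired_expression, paired_meta):
        with pytest.raises(DataValidationError, match="XIST"):
            verify_sex(paired_expression, paired_meta)

    def test_synthetic_cohort_has_no_flags(self):
        # samples with sex-consistent markers: males high RPS4Y1, females high XIST
        meta = [make_meta(f"s{i}", f"P{i}", sex="F" if i % 2 else "M") for i in range(6)]
        xist = [1.0 if i % 2 == 0 else 9.0 for i in range(6)]
        rps = [9.0 if i % 2 == 0 else 1.0 for i in range(6)]
        em = ExpressionMatrix(
            ["XIST", "RPS4Y1"], [m.sample_id for m in meta], np.array([xist, rps])
        )
        assert all(r.concordant for r in verify_sex(em, meta))
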