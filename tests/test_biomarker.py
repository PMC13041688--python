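"""Biomarker panel selection, PC1 scoring and group tests."""

import itertools

import numpy as np
import pytest

from voetx import (
    DataValidationError,
    DGEResult,
    ExpressionMatrix,
    GeneSetCollection,
    group_difference_test,
    patient_fold_changes,
    pc1_scores,
    select_biomarkers,
    wilcoxon_rank_sum,
)
from voetx.biomarker import PatientFoldChange
from voetx.enrichment import EnrichmentResult, SetEnrichment
from .conftest import make_meta


class TestPatientFoldChanges:
    def _cohort(self):
        meta = [
            make_meta("a1", "P1", "steady_state"),
            make_meta("a2", "P1", "voe"),
            make_meta("b1", "P2", "steady_state"),
            make_meta("b2", "P2", "voe"),
            make_meta("b3", "P2", "voe"),
            make_meta("c1", "P3", "steady_state"),  # no VOE -> excluded
        ]
        vals = np.array([[2.0, 5.0, 3.0, 4.0, 6.0, 1.0]])
        em = ExpressionMatrix(["g1"], [m.sample_id for m in meta], vals)
        return em, meta

    def test_single_pair_and_mean_rule(self):
        em, meta = self._cohort()
        pfc, excluded = patient_fold_changes(em, meta)
        by_subject = {p.subject_id: p for p in pfc}
        assert by_subject["P1"].delta[0] == pytest.approx(3.0)  # 5 - 2
        assert by_subject["P2"].delta[0] == pytest.approx(2.0)  # mean(4,6) - 3
        assert excluded == ["P3"]

    def test_no_paired_subjects_is_error(self):
        meta = [make_meta("a", "P1", "steady_state"), make_meta("b", "P2", "voe")]
        em = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 2.0]]))
        with pytest.raises(DataValidationError):
            patient_fold_changes(em, meta)


def make_selection_inputs(n_eligible=19, up_counts=(10, 9, 19, 12), in_set=(True, True, False, True),
                          adjp=(0.01, 0.01, 0.01, 0.2), lfc=(1.0, 1.0, 1.0, 1.0)):
    """Four candidate genes with configurable criterion outcomes."""
    genes = [f"g{i}" for i in range(4)]
    dge = DGEResult(
        gene_ids=genes,
        log2fc=np.asarray(lfc, float),
        amean=np.zeros(4),
        t=np.zeros(4),
        df_total=10.0,
        p=np.asarray(adjp, float),
        adj_p=np.asarray(adjp, float),
    )
    member_genes = [g for g, f in zip(genes, in_set) if f]
    gsc = GeneSetCollection({"SIG": ("d", member_genes or ["placeholder"])})
    enr = EnrichmentResult(
        sets=[SetEnrichment("SIG", len(member_genes), 0.8, 1.6, 0.001, 0.004, [])],
        skipped={},
    )
    rng = np.random.default_rng(0)
    pfc = []
    for s in range(n_eligible):
        delta = np.array(
            [1.0 if s < up_counts[i] else -1.0 for i in range(4)], dtype=float
        )
        pfc.append(PatientFoldChange(f"P{s}", delta, 1, 1))
    return pfc, dge, enr, gsc


class TestSelectBiomarkers:
    def test_strict_majority_of_19_requires_ten(self):
        pfc, dge, enr, gsc = make_selection_inputs()
        panel = select_biomarkers(pfc, dge, enr, gsc)
        # g0: 10/19 up -> majority met; g1: 9/19 -> fails; g2: not in set;
        # g3: not significant
        assert panel.gene_ids == ["g0"]
        assert panel.n_subjects_up["g0"] == 10
        assert panel.n_subjects_eligible == 19
        assert panel.pathway_membership["g0"] == ["SIG"]

    def test_upregulated_everywhere_but_no_pathway_is_excluded(self):
        pfc, dge, enr, gsc = make_selection_inputs(up_counts=(19, 0, 19, 0),
                                                   in_set=(False, True, False, True))
        panel = select_biomarkers(pfc, dge, enr, gsc)
        assert panel.gene_ids == []

    def test_negative_log2fc_is_excluded(self):
        pfc, dge, enr, gsc = make_selection_inputs(lfc=(-1.0, 1.0, 1.0, 1.0),
                                                   up_counts=(19, 19, 19, 19),
                                                   adjp=(0.01, 0.01, 0.01, 0.01),
                                                   in_set=(True, True, True, True))
        panel = select_biomarkers(pfc, dge, enr, gsc)
        assert "g0" not in panel.gene_ids

    def test_monotone_in_alpha(self):
        pfc, dge, enr, gsc = make_selection_inputs(adjp=(0.01, 0.03, 0.01, 0.2),
                                                   up_counts=(15, 15, 15, 15),
                                                   in_set=(True, True, True, True))
        tight = select_biomarkers(pfc, dge, enr, gsc, alpha=0.02)
        loose = select_biomarkers(pfc, dge, enr, gsc, alpha=0.05)
        assert set(tight.gene_ids) <= set(loose.gene_ids)

    def test_no_significant_sets_warns_with_empty_panel(self):
        pfc, dge, enr, gsc = make_selection_inputs()
        enr.sets[0].adj_p = 0.5
        panel = select_biomarkers(pfc, dge, enr, gsc)
        assert panel.gene_ids == []
        assert panel.warnings


class TestPC1Scores:
    def test_identical_rows_rank_one(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=12)
        em = ExpressionMatrix(
            [f"g{i}" for i in range(4)], [f"s{j}" for j in range(12)], np.tile(v, (4, 1))
        )
        ps = pc1_scores(em, em.gene_ids)
        assert ps.variance_explained == pytest.approx(1.0, abs=1e-10)
        std = (v - v.mean()) / v.std()
        assert np.corrcoef(ps.scores, std)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_negation_reverses_score_ranking(self):
        rng = np.random.default_rng(2)
        vals = np.tile(rng.normal(size=10), (4, 1)) + 0.05 * rng.normal(size=(4, 10))
        em = ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{j}" for j in range(10)], vals)
        neg = ExpressionMatrix(em.gene_ids, em.sample_ids, -vals)
        s1 = pc1_scores(em, em.gene_ids).scores
        s2 = pc1_scores(neg, em.gene_ids).scores
        assert np.allclose(np.argsort(s1), np.argsort(-s2))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 10))
        em = ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{j}" for j in range(10)], vals)
        perm = rng.permutation(10)
        em2 = em.subset_samples([em.sample_ids[i] for i in perm])
        s1 = pc1_scores(em, em.gene_ids)
        s2 = pc1_scores(em2, em.gene_ids)
        assert np.allclose(s1.scores[perm], s2.scores, atol=1e-10)

    def test_constant_gene_is_error(self):
        vals = np.vstack([np.ones(5), np.arange(5.0)])
        em = ExpressionMatrix(["g0", "g1"], [f"s{j}" for j in range(5)], vals)
        with pytest.raises(DataValidationError, match="g0"):
            pc1_scores(em, em.gene_ids)


class TestGroupTest:
    def test_hand_computed_pooled_t(self):
        t, p = group_difference_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_identical_groups(self):
        t, p = group_difference_test([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        t, p = group_difference_test([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert p == 0.0 and np.isinf(t)


class TestWilcoxon:
    def test_tiny_exact_example(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == pytest.approx(3.0)  # ranks 1 + 2
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_samples_with_ties_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert p == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 2), (5, 4)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = pooled[:n1], pooled[n1:]
        _, p = wilcoxon_rank_sum(x, y)
        # brute-force: rank-sum of x over all C(n1+n2, n1) assignments
        ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
        w_obs = ranks[:n1].sum()
        all_ranks = np.arange(1, n1 + n2 + 1)
        ws = [sum(c) for c in itertools.combinations(all_ranks, n1)]
        mean_w = n1 * (n1 + n2 + 1) / 2
        extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9 for w in ws)
        assert p == pytest.approx(extreme / len(ws), abs=1e-12)
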