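"""Ranking statistic, running-sum enrichment and per-sample pathway scores."""

import numpy as np
import pytest

from voetx import (
    DataValidationError,
    DGEResult,
    ExpressionMatrix,
    GeneSetCollection,
    RankedList,
    enrichment_score,
    gsea,
    rank_statistic,
    sample_scores,
)


def naive_walk_es(order_stats, member_mask, weight=1.0):
    """O(N*k) reference re-walk of the running sum."""
    n = len(order_stats)
    k = int(member_mask.sum())
    nr = float(np.sum(np.abs(order_stats[member_mask]) ** weight))
    walk, cur = [], 0.0
    for i in range(n):
        if member_mask[i]:
            cur += abs(order_stats[i]) ** weight / nr
        else:
            cur -= 1.0 / (n - k)
        walk.append(cur)
    walk = np.asarray(walk)
    pos, neg = walk.max(), walk.min()
    return pos if max(pos, 0) >= max(-neg, 0) else neg


def make_ranked(stats, ids=None):
    n = len(stats)
    ids = ids or [f"g{i:03d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-stats[i], ids[i]))
    return RankedList([ids[i] for i in order], np.asarray([stats[i] for i in order], float))


class TestRankStatistic:
    def _dge(self, adjp, lfc):
        n = len(adjp)
        return DGEResult(
            gene_ids=[f"g{i}" for i in range(n)],
            log2fc=np.asarray(lfc, float),
            amean=np.zeros(n),
            t=np.zeros(n),
            df_total=10.0,
            p=np.asarray(adjp, float),
            adj_p=np.asarray(adjp, float),
        )

    def test_direct_formula_values(self):
        rl = rank_statistic(self._dge([0.01, 1.0, 0.05], [2.0, 3.0, -1.0]))
        by_gene = dict(zip(rl.gene_ids, rl.statistics))
        assert by_gene["g0"] == pytest.approx(4.0)
        assert by_gene["g1"] == pytest.approx(0.0)
        assert by_gene["g2"] == pytest.approx(-np.log10(0.05) * -1.0)
        assert by_gene["g2"] == pytest.approx(-1.3010, abs=1e-4)

    def test_sorted_descending_with_lexicographic_ties(self):
        rl = rank_statistic(self._dge([1.0, 1.0, 0.01], [1.0, 2.0, 1.0]))
        assert rl.gene_ids[0] == "g2"
        assert rl.gene_ids[1:] == ["g0", "g1"]  # both 0.0, tie broken by id


class TestEnrichmentScore:
    def test_hand_walk_top_two(self):
        rl = make_ranked([5, 4, 3, 2, 1])
        es, leading, _ = enrichment_score(rl, rl.gene_ids[:2])
        assert es == pytest.approx(1.0, abs=1e-12)
        assert leading == rl.gene_ids[:2]

    def test_hand_walk_first_and_last(self):
        rl = make_ranked([5, 4, 3, 2, 1])
        es, _, _ = enrichment_score(rl, [rl.gene_ids[0], rl.gene_ids[4]])
        assert es == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_single_top_gene_scores_one(self):
        rl = make_ranked([9.0, 3.0, 2.0, 1.0, 0.5])
        es, _, _ = enrichment_score(rl, [rl.gene_ids[0]])
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        stats = rng.normal(size=40)
        rl1 = make_ranked(list(stats))
        rl2 = make_ranked(list(stats * 7.3))
        members = list(rng.choice(rl1.gene_ids, 8, replace=False))
        es1, _, _ = enrichment_score(rl1, members)
        es2, _, _ = enrichment_score(rl2, members)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_bounds_and_whole_universe_error(self):
        rl = make_ranked([3.0, 2.0, 1.0])
        with pytest.raises(DataValidationError):
            enrichment_score(rl, rl.gene_ids)
        with pytest.raises(DataValidationError):
            enrichment_score(rl, ["absent"])

    def test_matches_naive_rewalk_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(5, 50))
            stats = rng.normal(size=n) * rng.choice([0.1, 1, 10])
            rl = make_ranked(list(stats))
            k = int(rng.integers(1, min(10, n - 1) + 1))
            members = list(rng.choice(rl.gene_ids, k, replace=False))
            es, _, _ = enrichment_score(rl, members)
            mask = np.array([g in set(members) for g in rl.gene_ids])
            assert es == pytest.approx(naive_walk_es(rl.statistics, mask), abs=1e-12)
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestGSEA:
    def _random_instance(self, seed, n=300, n_sets=10):
        rng = np.random.default_rng(seed)
        rl = make_ranked(list(rng.normal(size=n)))
        sets = {
            f"S{i}": ("d", list(rng.choice(rl.gene_ids, 20, replace=False)))
            for i in range(n_sets)
        }
        return rl, GeneSetCollection(sets)

    def test_bitwise_reproducible_and_set_order_invariant(self):
        rl, gsc = self._random_instance(2)
        r1 = gsea(rl, gsc, n_perm=200, seed=5)
        r2 = gsea(rl, gsc, n_perm=200, seed=5)
        assert [(s.es, s.nes, s.p) for s in r1.sets] == [(s.es, s.nes, s.p) for s in r2.sets]
        reversed_gsc = GeneSetCollection(dict(reversed(list(gsc.sets.items()))))
        r3 = gsea(rl, reversed_gsc, n_perm=200, seed=5)
        by_name = {s.name: s for s in r3.sets}
        for s in r1.sets:
            assert by_name[s.name].p == s.p and by_name[s.name].nes == s.nes

    def test_es_field_matches_enrichment_score(self):
        rl, gsc = self._random_instance(3)
        res = gsea(rl, gsc, n_perm=150, seed=1)
        for s in res.sets:
            es, _, _ = enrichment_score(rl, gsc.genes(s.name))
            assert s.es == pytest.approx(es, abs=1e-12)
            assert np.sign(s.nes) == np.sign(s.es)

    def test_planted_top_set_is_significant(self):
        rng = np.random.default_rng(4)
        stats = np.abs(rng.normal(1.0, 0.5, size=500)) + 0.1
        rl = make_ranked(list(np.sort(stats)[::-1]))
        planted = rl.gene_ids[:25]
        sets = {"PLANTED": ("d", planted)}
        for i in range(9):
            sets[f"NULL{i}"] = ("d", list(rng.choice(rl.gene_ids, 25, replace=False)))
        res = gsea(rl, GeneSetCollection(sets), n_perm=2000, seed=7)
        planted_res = [s for s in res.sets if s.name == "PLANTED"][0]
        assert planted_res.nes > 0
        assert planted_res.adj_p < 0.05

    def test_oversized_and_disjoint_sets_are_skipped(self):
        rl = make_ranked([3.0, 2.0, 1.0, 0.5])
        gsc = GeneSetCollection(
            {"ALL": ("d", rl.gene_ids), "NONE": ("d", ["x", "y"]), "OK": ("d", rl.gene_ids[:2])}
        )
        res = gsea(rl, gsc, n_perm=100, seed=0)
        assert set(res.skipped) == {"ALL", "NONE"}
        assert [s.name for s in res.sets] == ["OK"]


class TestSampleScores:
    def test_constant_genes_score_near_zero(self):
        rng = np.random.default_rng(5)
        vals = np.tile(rng.normal(size=(30, 1)), (1, 8))  # constant across samples
        em = ExpressionMatrix([f"g{i}" for i in range(30)], [f"s{j}" for j in range(8)], vals)
        gsc = GeneSetCollection({"S": ("d", em.gene_ids[:10])})
        sm = sample_scores(em, gsc)
        assert np.max(np.abs(sm.scores)) < 0.3

    def test_shifted_module_separates_sample_groups(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            vals = rng.normal(size=(40, 10))
            vals[:8, 5:] += 1.5  # module up in the second half of samples
            em = ExpressionMatrix(
                [f"g{i}" for i in range(40)], [f"s{j}" for j in range(10)], vals
            )
            gsc = GeneSetCollection({"MOD": ("d", em.gene_ids[:8])})
            sm = sample_scores(em, gsc)
            hits += sm.scores[0, 5:].mean() > sm.scores[0, :5].mean()
        assert hits >= 48  # >= 95% of simulations

    def test_single_sample_is_error(self):
        em = ExpressionMatrix(["g1", "g2"], ["s1"], np.array([[1.0], [2.0]]))
        with pytest.raises(DataValidationError):
            sample_scores(em, GeneSetCollection({"S": ("d", ["g1"])}))

    def test_zscores_have_zero_mean(self):
        rng = np.random.default_rng(6)
        em = ExpressionMatrix(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(6)], rng.normal(size=(20, 6))
        )
        gsc = GeneSetCollection({"A": ("d", em.gene_ids[:5]), "B": ("d", em.gene_ids[5:10])})
        z = sample_scores(em, gsc).zscores()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
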