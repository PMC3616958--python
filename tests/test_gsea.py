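import numpy as np
import pytest

from pwcnaqtl.gsea import (
    RankedGeneList,
    enrichment_score,
    gsea_all,
    leading_edge,
    rank_genes,
)
from pwcnaqtl.io_model import Pathway, PathwayCollection, ValidationError
from tests.conftest import make_expression


def brute_force_es(genes, metric, members, weight_exponent):
    """Independent running-sum enumeration (the oracle)."""
    members = set(members)
    N = len(genes)
    n_hit = sum(g in members for g in genes)
    hit_total = sum(
        abs(m) ** weight_exponent for g, m in zip(genes, metric) if g in members
    )
    running, s = [], 0.0
    for g, m in zip(genes, metric):
        if g in members:
            if hit_total == 0:
                s += 1.0 / n_hit
            else:
                s += abs(m) ** weight_exponent / hit_total
        else:
            s -= 1.0 / (N - n_hit)
        running.append(s)
    best = max(range(N), key=lambda i: (abs(running[i]), -i))
    return running[best], running


def make_ranked(metrics, prefix="g"):
    order = sorted(range(len(metrics)), key=lambda i: -metrics[i])
    return RankedGeneList(
        [f"{prefix}{i}" for i in order], np.array([metrics[i] for i in order])
    )


class TestRankGenes:
    def test_derived_snr_value(self):
        # disease (4,4), control (2,2); sigma floored at 0.2|mu| per class
        vals = np.array([[4.0, 4.0, 2.0, 2.0], [1.0, 3.0, 2.0, 2.0]])
        E = make_expression(vals, n_disease=2)
        ranked = rank_genes(E)
        i = ranked.genes.index("G1")
        assert ranked.metric[i] == pytest.approx(2 / (0.8 + 0.4), abs=5e-4)
        assert round(ranked.metric[i], 3) == 1.667

    def test_equal_class_means_metric_zero_in_middle(self):
        vals = np.array(
            [
                [5.0, 7.0, 4.0, 8.0],  # equal means -> 0
                [9.0, 9.0, 1.0, 1.0],  # positive
                [1.0, 1.0, 9.0, 9.0],  # negative
            ]
        )
        E = make_expression(vals, n_disease=2)
        ranked = rank_genes(E)
        assert ranked.genes[0] == "G2" and ranked.genes[-1] == "G3"
        assert ranked.metric[ranked.genes.index("G1")] == pytest.approx(0.0)

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 9, size=(15, 8))
        E = make_expression(vals, n_disease=4)
        swapped = make_expression(
            np.concatenate([vals[:, 4:], vals[:, :4]], axis=1), n_disease=4
        )
        r1, r2 = rank_genes(E), rank_genes(swapped)
        m1 = dict(zip(r1.genes, r1.metric))
        m2 = dict(zip(r2.genes, r2.metric))
        for g in m1:
            assert m2[g] == pytest.approx(-m1[g], rel=1e-12, abs=1e-12)

    def test_small_class_errors(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        E = make_expression(vals, n_disease=1)
        with pytest.raises(ValidationError, match=">= 2 samples"):
            rank_genes(E)


class TestEnrichmentScore:
    def test_single_gene_rank1_es_one(self):
        ranked = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, [ranked.genes[0]], weight_exponent=0)
        assert res.es == pytest.approx(1.0)
        assert res.argmax_rank == 0

    def test_single_gene_rank_last_matches_oracle(self):
        ranked = make_ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        members = [ranked.genes[-1]]
        res = enrichment_score(ranked, members, weight_exponent=0)
        exp_es, exp_running = brute_force_es(ranked.genes, ranked.metric, members, 0)
        assert res.es == pytest.approx(exp_es)
        assert res.es < 0
        np.testing.assert_allclose(res.running, exp_running)

    def test_six_gene_list_oracle(self):
        ranked = make_ranked([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        members = [ranked.genes[1], ranked.genes[4]]  # ranks 2 and 5 (1-based)
        res = enrichment_score(ranked, members, weight_exponent=0)
        exp_es, _ = brute_force_es(ranked.genes, ranked.metric, members, 0)
        assert res.es == pytest.approx(exp_es)

    @pytest.mark.parametrize("w", [0.0, 1.0, 2.0])
    def test_random_instances_match_oracle(self, w):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            metrics = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(n)], metrics)
            size = int(rng.integers(1, min(4, n - 1) + 1))
            members = list(rng.choice(ranked.genes, size=size, replace=False))
            res = enrichment_score(ranked, members, weight_exponent=w)
            exp_es, exp_running = brute_force_es(ranked.genes, metrics, members, w)
            assert res.es == pytest.approx(exp_es, rel=1e-12, abs=1e-12)
            np.testing.assert_allclose(res.running, exp_running, atol=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(5, 12))
            metrics = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(n)], metrics)
            members = list(rng.choice(ranked.genes, size=2, replace=False))
            fwd = enrichment_score(ranked, members, weight_exponent=1)
            rev = RankedGeneList(ranked.genes[::-1], -metrics[::-1])
            bwd = enrichment_score(rev, members, weight_exponent=1)
            assert bwd.es == pytest.approx(-fwd.es, rel=1e-12, abs=1e-12)
            if fwd.es > 0:
                le_f = set(leading_edge(fwd, ranked).genes)
                le_b = set(leading_edge(bwd, rev).genes)
                assert le_f == le_b

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            metrics = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(n)], metrics)
            members = list(rng.choice(ranked.genes, size=3 if n > 4 else 2, replace=False))
            res = enrichment_score(ranked, members)
            assert abs(res.es) <= 1.0 + 1e-12

    def test_empty_intersection_errors(self):
        ranked = make_ranked([2.0, 1.0])
        with pytest.raises(ValidationError, match="empty intersection"):
            enrichment_score(ranked, ["nope"])

    def test_whole_list_errors(self):
        ranked = make_ranked([2.0, 1.0])
        with pytest.raises(ValidationError, match="entire ranked list"):
            enrichment_score(ranked, list(ranked.genes))


class TestLeadingEdge:
    def test_positive_es_takes_hits_up_to_argmax(self):
        # hits at ranks 2 and 5 (1-based) of 6; weighting puts the argmax at rank 2
        ranked = make_ranked([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        members = [ranked.genes[1], ranked.genes[4]]
        res = enrichment_score(ranked, members, weight_exponent=1)
        assert res.es > 0 and res.argmax_rank == 1
        le = leading_edge(res, ranked)
        assert le.sign == "over"
        assert le.genes == (ranked.genes[1],)

    def test_all_hits_before_argmax_gives_whole_intersection(self):
        ranked = make_ranked([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        members = [ranked.genes[0], ranked.genes[1]]
        res = enrichment_score(ranked, members, weight_exponent=0)
        le = leading_edge(res, ranked)
        assert set(le.genes) == set(members)

    def test_negative_es_mirror_of_positive_under_reversal(self):
        ranked = make_ranked([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        members = [ranked.genes[1], ranked.genes[4]]
        rev = RankedGeneList(ranked.genes[::-1], -ranked.metric[::-1])
        res = enrichment_score(rev, members, weight_exponent=1)
        assert res.es < 0
        le = leading_edge(res, rev)
        assert le.sign == "under"
        # oracle: the positive-case leading edge of the forward list
        fwd = enrichment_score(ranked, members, weight_exponent=1)
        assert set(le.genes) == set(leading_edge(fwd, ranked).genes)

    def test_leading_edge_subset_of_hits_nonempty(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = int(rng.integers(5, 14))
            metrics = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(n)], metrics)
            members = list(rng.choice(ranked.genes, size=3, replace=False))
            res = enrichment_score(ranked, members)
            if res.es == 0:
                continue
            le = leading_edge(res, ranked)
            assert set(le.genes) and set(le.genes) <= set(members)

    def test_es_zero_errors(self):
        ranked = make_ranked([3.0, 2.0, 1.0])
        res = enrichment_score(ranked, [ranked.genes[0]])
        res.es = 0.0
        with pytest.raises(ValidationError, match="degenerate"):
            leading_edge(res, ranked)


class TestGseaAll:
    def test_signs_and_skips(self):
        rng = np.random.default_rng(15)
        vals = rng.uniform(3, 7, size=(20, 10))
        vals[:5, :5] += 3.0  # genes 0-4 disease-up
        E = make_expression(vals, n_disease=5)
        pathways = PathwayCollection(
            [
                Pathway("UP", "", tuple(f"G{i}" for i in range(1, 5))),
                Pathway("ABSENT", "", ("ZZZ",)),
            ]
        )
        ranked, results, edges = gsea_all(E, pathways)
        assert [r.pathway for r in results] == ["UP"]
        assert results[0].es > 0
        assert edges[0].sign == "over"
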