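import math

import numpy as np
import pandas as pd
import pytest

from pwcnaqtl.downstream import (
    SharingMatrix,
    alteration_frequency,
    chromosome_sharing,
    differential_expression,
    driver_enrichment,
    fisher_over_representation,
    pathway_counts,
)
from pwcnaqtl.io_model import (
    CopyNumberMatrix,
    Pathway,
    PathwayCollection,
    ValidationError,
)
from pwcnaqtl.tagloci import TagLocus, TagLocusSet
from tests.conftest import make_expression


def make_cn(lg2_rows, chroms=None):
    lg2 = np.asarray(lg2_rows, dtype=float)
    m, n = lg2.shape
    idx = pd.Index([f"L{i + 1}" for i in range(m)], name="locus_id")
    return CopyNumberMatrix(
        pd.DataFrame(np.exp2(lg2), index=idx, columns=[f"S{j + 1}" for j in range(n)]),
        pd.DataFrame(
            {"chrom": chroms or ["chr1"] * m, "pos": [100 * (i + 1) for i in range(m)]},
            index=idx,
        ),
    )


def singleton_tags(CN):
    return TagLocusSet(
        [
            TagLocus(
                rep=lid,
                members=[lid],
                chrom=str(CN.coords.loc[lid, "chrom"]),
                span=(int(CN.coords.loc[lid, "pos"]), int(CN.coords.loc[lid, "pos"]) + 1),
            )
            for lid in CN.locus_ids
        ]
    )


def hypergeom_tail_oracle(overlap, set_size, draw_size, universe):
    total = math.comb(universe, draw_size)
    acc = 0
    for k in range(overlap, min(set_size, draw_size) + 1):
        acc += math.comb(set_size, k) * math.comb(universe - set_size, draw_size - k)
    return acc / total


class TestAlterationFrequency:
    def test_all_exceed(self):
        CN = make_cn([[2.0] * 5])
        freq = alteration_frequency(CN, singleton_tags(CN))
        assert freq["L1"] == 1.0

    def test_exactly_at_threshold_not_counted(self):
        CN = make_cn([[1.5, 2.0, -2.0, 0.0]])
        freq = alteration_frequency(CN, singleton_tags(CN))
        assert freq["L1"] == 0.5  # only the 2.0 and -2.0 entries

    def test_three_of_ten(self):
        lg2 = np.zeros((1, 10))
        lg2[0, :3] = [1.6, -1.7, 2.5]
        CN = make_cn(lg2)
        assert alteration_frequency(CN, singleton_tags(CN))["L1"] == 0.3

    def test_sample_order_invariant_and_monotone_in_threshold(self):
        rng = np.random.default_rng(71)
        lg2 = rng.normal(size=(4, 30))
        CN1 = make_cn(lg2)
        CN2 = make_cn(lg2[:, rng.permutation(30)])
        tags = singleton_tags(CN1)
        f1 = alteration_frequency(CN1, tags, threshold=1.0)
        f2 = alteration_frequency(CN2, tags, threshold=1.0)
        assert (f1 == f2).all()
        f_hi = alteration_frequency(CN1, tags, threshold=1.5)
        assert (f_hi <= f1).all()


class TestPathwayCounts:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["locus", "pathway", "significant"])

    def test_no_significant_all_zero(self):
        assoc = self._assoc([("L1", "P1", False), ("L2", "P1", False)])
        counts = pathway_counts(assoc)
        assert (counts == 0).all()

    def test_distinct_pathways_deduplicated(self):
        assoc = self._assoc(
            [("L1", "P1", True), ("L1", "P2", True), ("L1", "P2", True)]
        )
        assert pathway_counts(assoc)["L1"] == 2

    def test_counting_bound(self):
        assoc = self._assoc(
            [("L1", "P1", True), ("L2", "P2", True), ("L2", "P1", True)]
        )
        counts = pathway_counts(assoc)
        n_sig_pathways = assoc[assoc["significant"]]["pathway"].nunique()
        assert counts.sum() >= n_sig_pathways


class TestChromosomeSharing:
    def _tags(self):
        CN = make_cn(
            [[0.1] * 4, [0.2] * 4, [0.3] * 4],
            chroms=["chr7", "chr10", "chr4"],
        )
        return singleton_tags(CN)

    def test_single_pathway_two_chromosomes(self):
        assoc = pd.DataFrame(
            {
                "locus": ["L1", "L2"],
                "pathway": ["P", "P"],
                "significant": [True, True],
            }
        )
        sharing = chromosome_sharing(assoc, self._tags())
        c = sharing.counts
        assert c.loc["chr7", "chr10"] == 1 and c.loc["chr10", "chr7"] == 1
        assert c.loc["chr7", "chr7"] == 1 and c.loc["chr10", "chr10"] == 1
        assert c.loc["chr4", "chr4"] == 0

    def test_empty_table_zero_matrix(self):
        assoc = pd.DataFrame(
            {
                "locus": pd.Series(dtype=str),
                "pathway": pd.Series(dtype=str),
                "significant": pd.Series(dtype=bool),
            }
        )
        sharing = chromosome_sharing(assoc, self._tags())
        assert (sharing.counts.to_numpy() == 0).all()

    def test_diagonal_counts_distinct_pathways(self):
        assoc = pd.DataFrame(
            {
                "locus": ["L1", "L1", "L2"],
                "pathway": ["P1", "P2", "P1"],
                "significant": [True, True, True],
            }
        )
        sharing = chromosome_sharing(assoc, self._tags())
        assert sharing.counts.loc["chr7", "chr7"] == 2

    def test_unresolvable_locus_errors(self):
        assoc = pd.DataFrame(
            {"locus": ["LX"], "pathway": ["P"], "significant": [True]}
        )
        with pytest.raises(ValidationError, match="LX"):
            chromosome_sharing(assoc, self._tags())

    def test_symmetry_violation_rejected(self):
        bad = pd.DataFrame([[2, 1], [0, 2]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="symmetric"):
            SharingMatrix(bad)


class TestDriverEnrichment:
    def test_empty_overlap_p_is_one(self):
        p = fisher_over_representation(0, 10, 5, 50)
        assert p == pytest.approx(1.0)

    def test_paper_style_table_matches_tail_sum(self):
        p = fisher_over_representation(5, 10, 10, 100)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 10, 10, 100), rel=1e-10)

    def test_degenerate_everything_drivers(self):
        drivers = [f"G{i}" for i in range(5)]
        pws = PathwayCollection([Pathway("P", "", tuple(drivers))])
        records = driver_enrichment(pws, drivers, drivers)
        assert records[0].p == pytest.approx(1.0)
        assert records[0].overlap == 5

    def test_oracle_exhaustive_small_universe(self):
        for u in range(2, 16):
            for d in range(0, u + 1):
                for s in range(1, u + 1):
                    for k in range(max(0, d + s - u), min(d, s) + 1):
                        got = fisher_over_representation(k, s, d, u)
                        want = hypergeom_tail_oracle(k, s, d, u)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_sorted_by_p_then_name(self):
        genes = [f"G{i}" for i in range(30)]
        pws = PathwayCollection(
            [
                Pathway("B", "", tuple(genes[:10])),
                Pathway("A", "", tuple(genes[:10])),
                Pathway("C", "", tuple(genes[20:25])),
            ]
        )
        records = driver_enrichment(pws, genes[:8], genes)
        assert [r.pathway for r in records[:2]] == ["A", "B"]
        assert records[0].overlap <= min(records[0].pathway_size, records[0].driver_count)

    def test_empty_universe_errors(self):
        pws = PathwayCollection([Pathway("P", "", ("G1",))])
        with pytest.raises(ValidationError, match="universe"):
            driver_enrichment(pws, ["G1"], [])


class TestDifferentialExpression:
    def test_identical_groups_t0_p1(self):
        vals = np.array([[2.0, 2.0, 2.0, 2.0]])
        E = make_expression(vals, n_disease=2)
        de = differential_expression(E)
        assert de.loc["G1", "t"] == 0.0 and de.loc["G1", "p"] == 1.0
        assert bool(de.loc["G1", "degenerate"]) is True

    def test_welch_closed_form(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        E = make_expression(vals, n_disease=3)
        de = differential_expression(E)
        m1, m2 = 2.0, 5.0
        v1 = v2 = 1.0
        n1 = n2 = 3
        t_exp = (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)
        nu = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        from scipy import stats as st

        p_exp = 2 * st.t.sf(abs(t_exp), nu)
        assert de.loc["G1", "t"] == pytest.approx(t_exp, rel=1e-12)
        assert de.loc["G1", "p"] == pytest.approx(p_exp, rel=1e-12)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(72)
        vals = rng.uniform(1, 9, size=(10, 8))
        E = make_expression(vals, n_disease=4)
        swapped = make_expression(
            np.concatenate([vals[:, 4:], vals[:, :4]], axis=1), n_disease=4
        )
        d1, d2 = differential_expression(E), differential_expression(swapped)
        assert np.allclose(d1["t"], -d2["t"])
        assert np.allclose(d1["p"], d2["p"])
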