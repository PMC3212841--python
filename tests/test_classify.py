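"""LGT classes, contingency bookkeeping and the statistical engines."""
import numpy as np
import pytest

import lgtnet as L
from lgtnet.classify import (VERTICAL, WHOLE_GENE, WITHIN_GENE, UNCLASSIFIED,
                             GeneSetRecord, classify_gene_set,
                             co_transfer_analysis, fisher_association,
                             functional_enrichment, rank_sum_compare,
                             summarize)
from lgtnet.trn import RegulatoryNeighbourhood

from .oracles import fisher_two_sided, ranksum_two_sided


def _records(disc_orb, disc_noorb, conc_orb, conc_noorb, category="non-TF"):
    recs, i = [], 0
    for n, (d, o) in [(disc_orb, (True, True)), (disc_noorb, (True, False)),
                      (conc_orb, (False, True)), (conc_noorb, (False, False))]:
        for _ in range(n):
            recs.append(GeneSetRecord(f"f{i}", 10, d, o,
                                      regulator_category=category))
            i += 1
    return recs


class TestClassRule:
    @pytest.mark.parametrize("disc,orb,expected", [
        (True, True, WITHIN_GENE),
        (True, False, WHOLE_GENE),
        (False, True, WITHIN_GENE),   # cryptic: concordant yet ORB+
        (False, False, VERTICAL),
        (None, True, UNCLASSIFIED),
        (True, None, UNCLASSIFIED),
    ])
    def test_flag_pair_mapping(self, disc, orb, expected):
        assert classify_gene_set(disc, orb) == expected

    def test_lateral_is_none_for_unclassified(self):
        assert GeneSetRecord("f", 3, None, None).lateral is None


class TestSummarize:
    def test_totals_reconcile(self):
        t = summarize(_records(5, 3, 2, 7))
        assert t.n_classified == 17
        assert t.n_discordant + t.n_concordant == t.n_classified
        assert t.lateral_count + t.vertical_count == t.n_classified
        assert t.lateral_count == 10

    def test_all_vertical_gives_zero_lateral(self):
        t = summarize(_records(0, 0, 0, 9))
        assert t.lateral_count == 0 and t.vertical_count == 9

    def test_category_filter_restricts(self):
        recs = _records(1, 1, 1, 1, "neighbour") + _records(0, 0, 0, 5)
        t = summarize(recs, category_filter="neighbour")
        assert t.n_classified == 4 and t.lateral_count == 3

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="no records"):
            t = summarize([], category_filter="global")
        assert t.n_classified == 0

    def test_unclassified_counted_separately(self):
        recs = _records(1, 0, 0, 1) + [GeneSetRecord("x", 3, None, None)]
        t = summarize(recs)
        assert t.n_classified == 2 and t.unclassified == 1


class TestFisher:
    def test_neighbour_vs_other_orb_rates(self):
        # 19/90 neighbour ORB+ against 659/5192 elsewhere
        _, p, _ = fisher_association((19, 71), (659, 4533))
        assert p == pytest.approx(0.02, abs=0.005)

    def test_identical_proportions_give_p_one(self):
        _, p, _ = fisher_association((5, 5), (50, 50))
        assert p == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        _, p, cont = fisher_association((10, 0), (0, 10))
        assert cont is True
        assert p == pytest.approx(fisher_two_sided(10, 0, 0, 10), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_association((0, 5), (0, 7))

    def test_agrees_with_enumeration_on_sampled_small_tables(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p, _ = fisher_association((a, b), (c, d))
            assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-9)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        assert rank_sum_compare([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_triples_attain_minimal_p(self):
        # all 20 assignments: only the two extreme ones are as deviant
        assert rank_sum_compare([1, 1, 1], [9, 9, 9]) == pytest.approx(0.1)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n1, n2 = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = rng.integers(0, 5, n1).tolist()
            b = rng.integers(0, 5, n2).tolist()
            assert rank_sum_compare(a, b) == \
                pytest.approx(ranksum_two_sided(a, b), abs=1e-12)

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = [rank_sum_compare(rng.normal(size=30), rng.normal(size=30))
              for _ in range(60)]
        assert 0.01 < np.mean(np.array(ps) < 0.5) < 0.85

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_sum_compare([], [1.0])


class TestEnrichment:
    def test_concentrated_subset_overrepresented(self):
        cats = {f"g{i}": ("X" if i < 20 else "Y") for i in range(100)}
        df = functional_enrichment(cats, [f"g{i}" for i in range(15)])
        row = df[df.category == "X"].iloc[0]
        assert row.direction == "over" and row.significant

    def test_empty_subset_warns(self):
        cats = {"a": "X", "b": "Y"}
        with pytest.warns(UserWarning, match="empty subset"):
            df = functional_enrichment(cats, [])
        assert df.empty

    def test_uncategorised_subset_gene_rejected(self):
        with pytest.raises(ValueError, match="without a category"):
            functional_enrichment({"a": "X"}, ["zz"])

    def test_null_subset_flags_few_categories(self, rng):
        cats = {f"g{i}": f"c{i % 10}" for i in range(400)}
        flagged = 0
        for rep in range(20):
            sub = [f"g{i}" for i in rng.choice(400, 60, replace=False)]
            flagged += functional_enrichment(cats, sub).significant.sum()
        assert flagged / (20 * 10) < 0.15


class TestCoTransfer:
    def _hood(self, genes):
        return RegulatoryNeighbourhood(tf=genes[0],
                                       targets=list(genes[1:]),
                                       genes=list(genes))

    def test_clean_co_transfer_candidate(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 8, True, 1, rng)
        genes = ["tfA", "t1", "t2"]
        records = {g: GeneSetRecord(g, 8, True, False) for g in genes}
        trees = {g: tree for g in genes}
        v = co_transfer_analysis(self._hood(genes), records, trees)
        assert v.co_transfer_candidate
        assert v.contains_breakpoint is False

    def test_one_orb_positive_member_breaks_candidacy(self, species12, rng):
        tree, _ = L.simulate_gene_family(species12, 8, True, 1, rng)
        genes = ["tfA", "t1"]
        records = {"tfA": GeneSetRecord("tfA", 8, True, False),
                   "t1": GeneSetRecord("t1", 8, True, True)}
        trees = {g: tree for g in genes}
        v = co_transfer_analysis(self._hood(genes), records, trees)
        assert not v.co_transfer_candidate
        assert v.contains_breakpoint is True

    def test_insufficient_taxon_overlap_reports_na(self, rng):
        sp = L.simulate_species_tree(12, rng)
        t1 = sp.restrict(sorted(sp.leaves)[:6])
        t2 = sp.restrict(sorted(sp.leaves)[6:])
        genes = ["tfA", "t1"]
        records = {g: GeneSetRecord(g, 6, True, False) for g in genes}
        v = co_transfer_analysis(self._hood(genes), records,
                                 {"tfA": t1, "t1": t2})
        assert v.same_history is None

    def test_single_gene_neighbourhood_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            co_transfer_analysis(self._hood(["tfA"]), {}, {})
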