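"""Tree I/O, splits, rooting, collapsing and discordance calls."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import lgtnet as L
from lgtnet.phylo import NewickError, splits_compatible


class TestNewickIO:
    def test_supports_parsed_from_internal_labels(self, five_leaf):
        splits = five_leaf.splits()
        assert five_leaf.leaves == frozenset("ABCDE")
        assert sorted(splits.values()) == [0.97, 0.99]

    def test_roundtrip_preserves_topology_and_supports(self, five_leaf):
        again = L.parse_newick(five_leaf.to_newick())
        assert again.topology_key() == five_leaf.topology_key()
        assert again.splits() == five_leaf.splits()

    def test_duplicate_leaf_label_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            L.parse_newick("((A,B),(A,C),D);")

    @pytest.mark.parametrize("bad", ["((A,B),C;", "(A,B))C,D(;", "((A,B)"])
    def test_malformed_newick_reports_offset(self, bad):
        with pytest.raises(NewickError, match="offset"):
            L.parse_newick(bad)

    def test_file_roundtrip(self, tmp_path, rng):
        trees = [L.simulate_species_tree(n, rng) for n in (5, 9, 14)]
        path = tmp_path / "trees.nwk"
        L.write_newick(trees, path)
        back = L.read_newick(path)
        assert [t.topology_key() for t in back] == \
            [t.topology_key() for t in trees]

    @given(st.integers(0, 500))
    def test_random_tree_roundtrip_identity(self, seed):
        t = L.simulate_species_tree(4 + seed % 12, np.random.default_rng(seed))
        assert L.parse_newick(t.to_newick()).topology_key() == t.topology_key()


class TestSplits:
    def test_fully_resolved_tree_has_n_minus_3_splits(self, rng):
        for n in (4, 7, 13, 27):
            t = L.simulate_species_tree(n, rng)
            assert len(t.splits()) == n - 3

    def test_compatibility_rule(self):
        taxa = frozenset("ABCDEF")
        ab, abc = frozenset("AB"), frozenset("ABC")
        cd = frozenset("CD")
        bc = frozenset("BC")
        assert splits_compatible(ab, abc, taxa)     # nested
        assert splits_compatible(ab, cd, taxa)      # disjoint
        assert not splits_compatible(abc, bc | frozenset("D"), taxa)


class TestRooting:
    def test_root_on_leaf_edge(self):
        t = L.parse_newick("((A,B),(C,D));")
        r = L.root_tree(t, "A")
        assert r.root is not None
        # unrooted bipartitions unchanged
        assert r.unroot().topology_key() == t.topology_key()

    def test_root_on_clade(self):
        t = L.parse_newick("((A,B),(C,D),E);")
        r = L.root_tree(t, {"C", "D"})
        assert r.unroot().topology_key() == t.topology_key()

    def test_non_monophyletic_outgroup_rejected(self):
        t = L.parse_newick("((A,B),(C,D),E);")
        with pytest.raises(ValueError, match="monophyletic"):
            L.root_tree(t, {"A", "C"})


class TestCollapse:
    def test_full_support_unchanged(self, rng):
        t = L.simulate_species_tree(10, rng)
        assert t.collapse_low_support(0.95).topology_key() == t.topology_key()

    def test_all_low_support_gives_star(self):
        t = L.parse_newick("((A,B)0.5,(C,D)0.5,E);")
        assert t.collapse_low_support(0.95).splits() == {}

    def test_threshold_is_inclusive(self):
        t = L.parse_newick("((A,B)0.95,(C,D)0.94,E);")
        kept = t.collapse_low_support(0.95).splits()
        # the edge at exactly 0.95 (split AB|CDE, canonical side CDE) stays;
        # the 0.94 edge (split CD|ABE) is contracted
        assert set(kept) == {frozenset("CDE")}


class TestDiscordance:
    def test_restricted_reference_is_concordant(self, species12, rng):
        fam, _ = L.simulate_gene_family(species12, 8, False, 0, rng)
        assert not L.is_discordant(fam, species12)

    def test_planted_transfer_is_discordant(self, species12, rng):
        fam, _ = L.simulate_gene_family(species12, 8, True, 1, rng)
        assert L.is_discordant(fam, species12)

    def test_conflict_below_threshold_collapses_away(self):
        ref = L.parse_newick("((A,B),(C,D),E);")
        test = L.parse_newick("((A,C)0.80,(B,D)0.80,E);")
        assert not L.is_discordant(test, ref, threshold=0.95)
        strong = L.parse_newick("((A,C)0.99,(B,D)0.99,E);")
        assert L.is_discordant(strong, ref, threshold=0.95)

    def test_too_few_shared_taxa_rejected(self):
        ref = L.parse_newick("((A,B),(C,D),E);")
        test = L.parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="4 shared"):
            L.is_discordant(test, ref)

    def test_restriction_happens_before_comparison(self, rng):
        sp = L.simulate_species_tree(15, rng)
        fam, _ = L.simulate_gene_family(sp, 6, False, 0, rng)
        assert not L.is_discordant(fam, sp)
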