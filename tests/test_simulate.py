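"""Determinism and label consistency of the synthetic-data generator."""
import numpy as np
import pytest

import lgtnet as L
from lgtnet.simulate import (SimConfig, simulate_alignment, simulate_cohort,
                             simulate_gene_family, simulate_species_tree)


def _small_config(seed=0):
    return SimConfig(n_families=12, n_strains=10, family_size_max=10,
                     n_tfs=12, n_targets=60, n_edges=150, k_global=3,
                     n_heterodimer_global=1, n_neighbour=4, seed=seed)


class TestSpeciesTree:
    @pytest.mark.parametrize("n,edges", [(4, 1), (10, 7), (27, 24)])
    def test_internal_edge_count(self, n, edges):
        t = simulate_species_tree(n, seed=1)
        assert len(t.internal_edges()) == edges
        assert t.is_binary()

    def test_same_seed_same_newick(self):
        assert simulate_species_tree(15, seed=9).to_newick() == \
            simulate_species_tree(15, seed=9).to_newick()

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(3, seed=0)


class TestGeneFamily:
    def test_vertical_family_concordant(self, species12, rng):
        tree, truth = simulate_gene_family(species12, 8, False, 0, rng)
        assert not L.is_discordant(tree, species12)
        assert truth["spr_moves"] == 0

    def test_single_move_family_at_distance_one(self, species12, rng):
        tree, _ = simulate_gene_family(species12, 8, True, 1, rng)
        assert L.spr_edit_distance(tree, species12).distance == 1

    def test_moves_without_lateral_flag_rejected(self, species12, rng):
        with pytest.raises(ValueError):
            simulate_gene_family(species12, 8, False, 2, rng)

    def test_supports_drawn_high(self, species12, rng):
        tree, _ = simulate_gene_family(species12, 9, True, 1, rng)
        sups = [tree.edge_support(*tuple(e)) for e in tree.internal_edges()]
        assert all(s >= 0.95 for s in sups)


class TestAlignmentSim:
    def test_zero_divergence_identical_sequences(self, species12, rng):
        tree, _ = simulate_gene_family(species12, 6, False, 0, rng)
        aln, _ = simulate_alignment([tree], 120, 0.0, (), rng)
        assert len(set(aln.sequences.values())) == 1

    def test_short_segment_rejected(self, species12, rng):
        tree, _ = simulate_gene_family(species12, 6, False, 0, rng)
        with pytest.raises(ValueError, match="30 columns"):
            simulate_alignment([tree, tree], 100, 1.0, [80], rng)

    def test_segment_tree_count_must_match(self, species12, rng):
        tree, _ = simulate_gene_family(species12, 6, False, 0, rng)
        with pytest.raises(ValueError, match="one tree per segment"):
            simulate_alignment([tree], 300, 1.0, [150], rng)


class TestCohort:
    def test_full_determinism_byte_identical(self):
        c1 = simulate_cohort(_small_config(seed=4))
        c2 = simulate_cohort(_small_config(seed=4))
        assert c1.species_tree.to_newick() == c2.species_tree.to_newick()
        for f1, f2 in zip(c1.families, c2.families):
            assert f1.tree.to_newick() == f2.tree.to_newick()
            assert f1.alignment.sequences == f2.alignment.sequences
            assert f1.truth == f2.truth
        assert c1.gene_family_map == c2.gene_family_map

    def test_different_seeds_differ(self):
        c1 = simulate_cohort(_small_config(seed=1))
        c2 = simulate_cohort(_small_config(seed=2))
        assert c1.species_tree.to_newick() != c2.species_tree.to_newick()

    def test_labels_consistent_with_data(self):
        cohort = simulate_cohort(_small_config(seed=8))
        for f in cohort.families:
            cls = f.truth["lgt_class"]
            if cls == "within_gene_lateral":
                assert len(f.truth["breakpoints"]) >= 1
                assert f.truth["spr_moves"] >= 1
            elif cls == "whole_gene_lateral":
                assert f.truth["breakpoints"] == []
                assert f.truth["spr_moves"] >= 1
            else:
                assert f.truth["spr_moves"] == 0
            assert 4 <= f.size <= 10

    def test_class_mix_matches_config_fractions(self):
        cfg = _small_config(seed=3)
        cohort = simulate_cohort(cfg)
        classes = [f.truth["lgt_class"] for f in cohort.families]
        n_mosaic = classes.count("within_gene_lateral")
        n_lateral = sum(c != "vertical" for c in classes)
        assert n_mosaic == round(cfg.n_families * cfg.breakpoint_fraction)
        assert n_lateral == round(cfg.n_families * cfg.lgt_fraction)
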