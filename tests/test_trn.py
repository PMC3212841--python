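"""Regulatory-network construction, metrics and regulator classification."""
import numpy as np
import pytest

import lgtnet as L
from lgtnet.simulate import SimConfig, simulate_trn
from lgtnet.trn import (GeneLocus, RegulatoryNetwork, build_trn,
                        classify_global, extract_neighbourhood,
                        find_neighbour_regulators, read_loci)


def _write_edges(path, rows):
    path.write_text("# regulator\ttarget\teffect\tevidence\n" +
                    "\n".join("\t".join(r) for r in rows) + "\n")


def _net(edges, het=()):
    net = RegulatoryNetwork(heterodimer_groups=het)
    for u, v in edges:
        net.add_edge(u, v)
    return net


def _loci(order):
    return {g: GeneLocus(g, "chr", 1000 * i, 1000 * i + 900, "+", i)
            for i, g in enumerate(order)}


class TestBuild:
    def test_duplicate_edges_deduplicated(self, tmp_path):
        p = tmp_path / "e.tsv"
        _write_edges(p, [("A", "B", "+", "x"), ("A", "C", "+", "x"),
                         ("A", "B", "-", "y")])
        net = build_trn(p)
        assert net.n_edges == 2 and net.out_degree("A") == 2

    def test_excluded_genes_dropped_and_reported(self, tmp_path):
        p = tmp_path / "e.tsv"
        _write_edges(p, [("A", "B", "+", "x"), ("A", "rnaX", "+", "x")])
        net = build_trn(p, exclusion={"rnaX"})
        assert net.out_degree("A") == 1
        assert ("A", "rnaX", "excluded target") in net.skipped

    def test_heterodimer_subunits_share_targets(self, tmp_path):
        p = tmp_path / "e.tsv"
        targets = [f"t{i}" for i in range(5)]
        _write_edges(p, [("IhfAB", t, "+", "x") for t in targets])
        net = build_trn(p, subunit_map={"IhfAB": ["ihfA", "ihfB"]})
        assert net.out_degree("ihfA") == 5 and net.out_degree("ihfB") == 5
        assert net.heterodimer_partners("ihfA") == {"ihfB"}

    def test_tf_tf_file_merged(self, tmp_path):
        p1, p2 = tmp_path / "tg.tsv", tmp_path / "tt.tsv"
        _write_edges(p1, [("A", "b1", "+", "x")])
        _write_edges(p2, [("A", "B", "+", "x"), ("B", "b2", "+", "x")])
        net = build_trn(p1, p2)
        assert net.tf_set == {"A", "B"}
        assert net.n_edges == 3


class TestMetrics:
    def test_star_out_degree_and_leaf_betweenness(self):
        net = _net([("hub", f"t{i}") for i in range(6)])
        assert net.out_degree("hub") == 6
        assert all(net.betweenness(f"t{i}") == 0.0 for i in range(6))

    def test_chain_betweenness_counts_ordered_pairs(self):
        net = _net([("A", "B"), ("B", "C")])
        assert net.betweenness("B") == 1.0

    def test_unknown_node_rejected(self):
        net = _net([("A", "B")])
        with pytest.raises(KeyError):
            net.out_degree("Z")

    def test_degree_sum_equals_edge_count(self):
        net = _net([("A", "B"), ("A", "C"), ("B", "C"), ("C", "A")])
        total = sum(net.out_degree(n) for n in net.nodes)
        assert total == net.n_edges


class TestGlobalClassification:
    def test_top_k_by_out_degree(self):
        edges = []
        for tf, deg in [("a", 9), ("b", 7), ("c", 5), ("d", 3)]:
            edges += [(tf, f"{tf}{i}") for i in range(deg)]
        assert classify_global(_net(edges), k=2) == {"a", "b"}

    def test_k_larger_than_tf_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            classify_global(_net([("a", "x")]), k=5)

    def test_boundary_tie_includes_all_and_warns(self):
        edges = []
        for tf, deg in [("a", 9), ("b", 5), ("c", 5), ("d", 3)]:
            edges += [(tf, f"{tf}{i}") for i in range(deg)]
        with pytest.warns(UserWarning, match="tie"):
            out = classify_global(_net(edges), k=2)
        assert out == {"a", "b", "c"}

    def test_heterodimer_unit_counts_once(self):
        edges = []
        targets = [f"t{i}" for i in range(8)]
        for g in ("h1", "h2"):
            edges += [(g, t) for t in targets]
        for tf, deg in [("a", 6), ("b", 4)]:
            edges += [(tf, f"{tf}{i}") for i in range(deg)]
        net = _net(edges, het=[frozenset({"h1", "h2"})])
        out = classify_global(net, k=2)
        assert out == {"h1", "h2", "a"}  # 2 units -> 3 genes


class TestNeighbourRegulators:
    def test_adjacent_target_detected(self):
        order = [f"g{i}" for i in range(20)]
        net = _net([("g10", "g11"), ("g10", "g15")])
        assert find_neighbour_regulators(net, _loci(order)) == {"g10"}

    def test_distal_only_regulator_not_neighbour(self):
        order = [f"g{i}" for i in range(50)]
        net = _net([("g10", "g40")])
        assert find_neighbour_regulators(net, _loci(order)) == set()

    def test_global_regulators_excluded(self):
        order = [f"g{i}" for i in range(20)]
        net = _net([("g10", "g11")])
        assert find_neighbour_regulators(net, _loci(order),
                                         global_set={"g10"}) == set()

    def test_circular_wraparound_adjacency(self):
        order = [f"g{i}" for i in range(10)]
        net = _net([("g0", "g9")])
        assert find_neighbour_regulators(net, _loci(order)) == {"g0"}

    def test_self_regulation_not_adjacency(self):
        order = [f"g{i}" for i in range(10)]
        net = _net([("g3", "g3"), ("g3", "g8")])
        assert find_neighbour_regulators(net, _loci(order)) == set()

    def test_adjacent_heterodimer_pair_regulating_only_each_other_excluded(self):
        order = [f"g{i}" for i in range(10)]
        net = _net([("g3", "g4"), ("g4", "g3")],
                   het=[frozenset({"g3", "g4"})])
        assert find_neighbour_regulators(net, _loci(order)) == set()
        # ... but not when one also regulates another adjacent gene
        net2 = _net([("g3", "g4"), ("g4", "g3"), ("g3", "g2")],
                    het=[frozenset({"g3", "g4"})])
        assert "g3" in find_neighbour_regulators(net2, _loci(order))

    def test_missing_locus_skipped_with_warning(self):
        order = [f"g{i}" for i in range(10)]
        net = _net([("zz", "g1"), ("g4", "g5")])
        with pytest.warns(UserWarning, match="zz"):
            out = find_neighbour_regulators(net, _loci(order))
        assert out == {"g4"}


class TestNeighbourhoods:
    def test_long_collinear_run(self):
        order = [f"g{i}" for i in range(30)]
        net = _net([("g5", f"g{i}") for i in range(6, 20)])
        hood = extract_neighbourhood(net, _loci(order), "g5")
        assert len(hood.targets) == 14
        assert hood.genes[0] == "g5"

    def test_single_adjacent_target_gives_size_two(self):
        order = [f"g{i}" for i in range(10)]
        net = _net([("g5", "g6")])
        hood = extract_neighbourhood(net, _loci(order), "g5")
        assert hood.genes == ["g5", "g6"] and hood.size == 2

    def test_run_truncated_at_unregulated_gap(self):
        order = [f"g{i}" for i in range(20)]
        net = _net([("g5", "g6"), ("g5", "g8")])  # g7 not regulated
        hood = extract_neighbourhood(net, _loci(order), "g5")
        assert hood.targets == ["g6"]

    def test_upstream_and_downstream_targets_combined(self):
        order = [f"g{i}" for i in range(20)]
        net = _net([("g5", "g4"), ("g5", "g6"), ("g5", "g7")])
        hood = extract_neighbourhood(net, _loci(order), "g5")
        assert hood.genes == ["g4", "g5", "g6", "g7"]


class TestLociLoader:
    def test_ranks_follow_start_order(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("b\tchr\t5000\t5900\t+\na\tchr\t100\t900\t-\n"
                     "c\tchr\t9000\t9900\t+\n")
        loci = read_loci(p)
        assert [loci[g].rank for g in "abc"] == [0, 1, 2]


class TestSimulatedNetwork:
    def test_planted_categories_partition_and_recover(self):
        cfg = SimConfig(n_tfs=40, n_targets=220, n_edges=700, k_global=6,
                        n_heterodimer_global=1, n_neighbour=15, seed=5)
        net, loci, truth = simulate_trn(cfg, np.random.default_rng(5))
        glob = classify_global(net, k=cfg.k_global)
        nbr = find_neighbour_regulators(net, loci, glob)
        other = net.tf_set - glob - nbr
        assert glob == truth["global"]
        assert nbr == truth["neighbour"]
        assert other == truth["other"]
        assert not (glob & nbr) and not (glob & other) and not (nbr & other)
        assert glob | nbr | other == net.tf_set

    def test_hub_edge_share_increases_with_tail_heaviness(self):
        shares = []
        for share in (0.4, 0.6, 0.8):
            cfg = SimConfig(n_tfs=40, n_targets=220, n_edges=700, k_global=6,
                            n_heterodimer_global=0, n_neighbour=10,
                            hub_edge_share=share, seed=2)
            net, loci, truth = simulate_trn(cfg, np.random.default_rng(2))
            hub_edges = sum(net.out_degree(g) for g in truth["global"])
            shares.append(hub_edges / net.n_edges)
        assert shares[0] < shares[1] < shares[2]
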