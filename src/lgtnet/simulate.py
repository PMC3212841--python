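"""Synthetic study generator: species tree, gene families, mosaic
alignments and a regulatory network — all with ground-truth labels.

The generator emulates the study conditions at desk scale: a clade of 27
strains; single-copy families of 4-27 taxa; roughly half the families
lateral, of which a quarter carry an observable within-gene breakpoint;
transfers planted as 1-9 SPR moves weighted so that most lateral families
need at most two; and a regulatory network of 179 TF genes and 1533 targets
whose out-degree distribution is heavy-tailed, with 20 hub units enacting
about two-thirds of all regulation and 93 TFs placed adjacent to short runs
of collinear targets.

Everything is deterministic given the configuration seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import Alignment
from .phylo import PhyloTree
from .spr import random_spr
from .trn import GeneLocus, RegulatoryNetwork

_CATEGORIES = (
    "Hypothetical proteins", "Energy metabolism", "Transport and binding",
    "Protein synthesis", "Regulatory functions", "Cell envelope",
    "Mobile element functions", "Unclassified",
)


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort."""

    n_strains: int = 27
    n_families: int = 200
    family_size_min: int = 4
    family_size_max: int = 27
    lgt_fraction: float = 0.503          # lateral share of families
    breakpoint_fraction: float = 0.128   # ORB+ share of families
    spr_move_weights: tuple = (0.55, 0.20, 0.10, 0.05, 0.04,
                               0.02, 0.02, 0.01, 0.01)  # moves 1..9
    alignment_codons: int = 200
    branch_scale: float = 0.03           # mean edge length, subs/site
    divergence: float = 1.0              # global branch-length multiplier
    n_tfs: int = 179
    n_targets: int = 1533
    n_edges: int = 3804
    k_global: int = 20
    n_heterodimer_global: int = 2
    n_neighbour: int = 93
    hub_edge_share: float = 0.688
    max_run_length: int = 14
    seed: int = 0

    def __post_init__(self):
        for f in (self.lgt_fraction, self.breakpoint_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.family_size_min < 4:
            raise ValueError("family sizes below 4 are not phylogenetically "
                             "meaningful")
        if self.n_targets < self.n_tfs:
            raise ValueError("n_targets must be >= n_tfs")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spr_move_weights"] = list(self.spr_move_weights)
        return d


@dataclass
class FamilyData:
    """One simulated gene family with its ground truth."""

    family: str
    size: int
    tree: PhyloTree
    alignment: Alignment
    truth: dict


@dataclass
class Cohort:
    config: SimConfig
    species_tree: PhyloTree
    families: list
    trn: RegulatoryNetwork
    loci: dict
    tf_truth: dict           # category -> set of TF genes
    gene_family_map: dict    # TRN gene -> family id (TF genes only)
    gene_categories: dict    # TRN gene -> functional category


def _strain_labels(n: int) -> list:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_species_tree(n_strains: int, seed=None,
                          branch_scale: float = 0.03) -> PhyloTree:
    """Random binary unrooted tree with exponential branch lengths and
    full support on every internal edge."""
    if n_strains < 4:
        raise ValueError("need >= 4 strains")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = _strain_labels(n_strains)
    t = PhyloTree()
    center = t.add_node()
    for lab in labels[:3]:
        t.add_edge(t.add_node(lab), center)
    for lab in labels[3:]:
        edges = sorted(t.edges(), key=lambda e: tuple(sorted(e)))
        u, v = tuple(edges[rng.integers(len(edges))])
        t.remove_edge(u, v)
        mid = t.add_node()
        leaf = t.add_node(lab)
        t.add_edge(u, mid)
        t.add_edge(v, mid)
        t.add_edge(leaf, mid)
    for e in t.edges():
        u, v = tuple(e)
        t.set_edge_length(u, v, float(rng.exponential(branch_scale) + 0.005))
        if all(not t.is_leaf(w) for w in e):
            t.set_edge_support(u, v, 1.0)
    return t


def simulate_gene_family(species_tree: PhyloTree, size: int, lateral: bool,
                         spr_moves: int = 0, rng=None,
                         support_low: float = 0.95) -> tuple:
    """Restrict the species tree to a random taxon subset and, for lateral
    families, apply the requested number of non-identity SPR moves.
    Internal-edge supports are drawn high (>= ``support_low``) so planted
    discordance is detectable after support collapsing."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    leaves = sorted(species_tree.leaves)
    if not 4 <= size <= len(leaves):
        raise ValueError(f"family size must be in [4, {len(leaves)}]")
    if spr_moves > 0 and not lateral:
        raise ValueError("spr_moves > 0 requires lateral=True")
    if lateral and spr_moves < 1:
        raise ValueError("a lateral family needs >= 1 SPR move")
    taxa = [leaves[i] for i in rng.choice(len(leaves), size, replace=False)]
    tree = species_tree.restrict(taxa)
    for _ in range(spr_moves):
        tree = random_spr(tree, rng)
    for e in tree.internal_edges():
        u, v = tuple(e)
        tree.set_edge_support(u, v, float(rng.uniform(support_low, 1.0)))
    truth = {"lateral": lateral, "spr_moves": spr_moves, "taxa": sorted(taxa)}
    return tree, truth


def _evolve_segment(tree: PhyloTree, length: int, divergence: float,
                    rng) -> dict:
    """Evolve one alignment segment along a tree under Jukes-Cantor."""
    root = next(v for v in tree.nodes() if not tree.is_leaf(v))
    seqs: dict = {}
    root_seq = rng.integers(0, 4, size=length)
    stack = [(root, None, root_seq)]
    while stack:
        v, parent, seq = stack.pop()
        if tree.is_leaf(v):
            seqs[tree.label_of(v)] = seq
        for u in sorted(tree.neighbours(v)):
            if u == parent:
                continue
            bl = tree.edge_length(v, u)
            bl = 0.05 if bl is None else bl
            stay = np.exp(-4.0 * bl * divergence / 3.0)
            child = seq.copy()
            mut = rng.random(length) >= stay
            child[mut] = rng.integers(0, 4, size=int(mut.sum()))
            stack.append((u, v, child))
    return seqs


def simulate_alignment(trees, length: int, divergence: float = 1.0,
                       breakpoints=(), rng=None) -> tuple:
    """Simulate a (possibly mosaic) nucleotide alignment.

    ``trees`` is one tree per segment; ``breakpoints`` are the 0-based left
    edges of each segment after the first.  Segments shorter than 30 columns
    are refused (they are undetectable by design).
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    if isinstance(trees, PhyloTree):
        trees = [trees]
    breakpoints = list(breakpoints)
    if len(trees) != len(breakpoints) + 1:
        raise ValueError("need one tree per segment")
    bounds = [0] + breakpoints + [length]
    if any(b <= a for a, b in zip(bounds, bounds[1:])):
        raise ValueError("breakpoints must be increasing within the alignment")
    if any(e - s < 30 for s, e in zip(bounds[:-1], bounds[1:])):
        raise ValueError("segments shorter than 30 columns are not allowed")
    labels = sorted(trees[0].leaves)
    if any(sorted(t.leaves) != labels for t in trees):
        raise ValueError("all segment trees must share one taxon set")
    parts = {lab: [] for lab in labels}
    for tree, s, e in zip(trees, bounds[:-1], bounds[1:]):
        seg = _evolve_segment(tree, e - s, divergence, rng)
        for lab in labels:
            parts[lab].append(seg[lab])
    alphabet = np.array(list("ACGT"))
    seqs = {lab: "".join(alphabet[np.concatenate(parts[lab])])
            for lab in labels}
    truth = {"breakpoints": breakpoints, "n_segments": len(trees)}
    return Alignment(seqs), truth


# -- regulatory network -----------------------------------------------------

def _circular_distance(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def simulate_trn(config: SimConfig, rng=None) -> tuple:
    """Generate the network, gene coordinates and true regulator categories.

    Hub units get out-degrees well above every non-hub TF so the top-k rule
    recovers them exactly; neighbour TFs sit next to a planted run of 1-14
    collinear targets; all remaining wiring is kept at circular rank
    distance >= 2 so no distal-only TF is accidentally a neighbour.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    tf_genes = [f"tf{i + 1:03d}" for i in range(config.n_tfs)]
    tg_genes = [f"tg{i + 1:04d}" for i in range(config.n_targets)]
    order_tf = [tf_genes[i] for i in rng.permutation(config.n_tfs)]

    n_hub_genes = config.k_global + config.n_heterodimer_global
    hub_genes = order_tf[:n_hub_genes]
    het_groups = [frozenset(hub_genes[2 * i:2 * i + 2])
                  for i in range(config.n_heterodimer_global)]
    hub_units = list(het_groups) + [frozenset([g])
                                    for g in hub_genes[2 * config.n_heterodimer_global:]]
    neighbour_tfs = order_tf[n_hub_genes:n_hub_genes + config.n_neighbour]
    other_tfs = order_tf[n_hub_genes + config.n_neighbour:]

    # out-degrees: hubs share ~hub_edge_share of all edges, everyone else
    # a capped heavy tail strictly below the hub floor
    hub_edges = int(round(config.n_edges * config.hub_edge_share))
    raw = rng.pareto(1.2, size=len(hub_units)) + 1.0
    hub_deg = np.maximum(40, (raw / raw.sum() * hub_edges).astype(int))
    nonhub = neighbour_tfs + other_tfs
    nonhub_deg = {tf: int(min(30, rng.zipf(1.7))) for tf in nonhub}

    run_lengths = {tf: int(min(config.max_run_length, rng.zipf(2.5)))
                   for tf in neighbour_tfs}

    # chromosome layout: neighbour blocks separated by >= 1 spacer gene
    tg_pool = list(tg_genes)
    blocks = []
    for tf in neighbour_tfs:
        run = [tg_pool.pop() for _ in range(run_lengths[tf])]
        blocks.append((tf, run))
    spacers = hub_genes + other_tfs + tg_pool
    if len(spacers) < len(blocks):
        raise ValueError("infeasible placement: not enough spacer genes")
    spacer_idx = rng.permutation(len(spacers))
    spacers = [spacers[i] for i in spacer_idx]
    per_gap = np.ones(len(blocks), dtype=int)
    extra = len(spacers) - len(blocks)
    if extra > 0:
        per_gap += np.bincount(rng.integers(0, len(blocks), size=extra),
                               minlength=len(blocks))
    order: list = []
    run_of: dict = {}
    si = 0
    for (tf, run), gap in zip(blocks, per_gap):
        if rng.random() < 0.5:
            order.extend([tf] + run)
        else:
            order.extend(run + [tf])
        run_of[tf] = run
        order.extend(spacers[si:si + gap])
        si += gap
    assert len(order) == config.n_tfs + config.n_targets
    pos = {g: i for i, g in enumerate(order)}
    N = len(order)
    loci = {g: GeneLocus(g, "chr", 1000 * i, 1000 * i + 900,
                         "+" if rng.random() < 0.5 else "-", i)
            for i, g in enumerate(order)}

    net = RegulatoryNetwork(heterodimer_groups=het_groups)

    def sample_targets(tf_or_unit, n_wanted, pool, min_dist):
        anchor = sorted(tf_or_unit)[0] if isinstance(tf_or_unit, frozenset) \
            else tf_or_unit
        members = set(tf_or_unit) if isinstance(tf_or_unit, frozenset) \
            else {tf_or_unit}
        elig = [g for g in pool
                if g not in members
                and _circular_distance(pos[anchor], pos[g], N) >= min_dist]
        n_wanted = min(n_wanted, len(elig))
        idx = rng.choice(len(elig), size=n_wanted, replace=False)
        return [elig[i] for i in idx]

    for unit, deg in zip(hub_units, hub_deg):
        targets = sample_targets(unit, int(deg), tg_genes + tf_genes, 0)
        for g in unit:
            for t in targets:
                net.add_edge(g, t)
    for tf in neighbour_tfs:
        run = run_of[tf]
        for t in run:
            net.add_edge(tf, t)
        extra_n = max(0, nonhub_deg[tf] - len(run))
        # keep the flanks of the planted block clean so the true run stays
        # exactly the planted one
        for t in sample_targets(tf, extra_n, tg_genes,
                                min_dist=len(run) + 2):
            net.add_edge(tf, t)
    for tf in other_tfs:
        for t in sample_targets(tf, nonhub_deg[tf], tg_genes, min_dist=2):
            net.add_edge(tf, t)

    truth = {"global": set(hub_genes), "neighbour": set(neighbour_tfs),
             "other": set(other_tfs),
             "run_of": {tf: list(r) for tf, r in run_of.items()}}
    return net, loci, truth


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic study: trees, alignments, network,
    coordinates, category labels and the TF-gene -> family mapping."""
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_fam, rng_trn, rng_map = \
        (np.random.default_rng(c) for c in ss.spawn(4))

    species = simulate_species_tree(config.n_strains, rng_tree,
                                    config.branch_scale)
    n = config.n_families
    n_mosaic = int(round(n * config.breakpoint_fraction))
    n_lateral = int(round(n * config.lgt_fraction))
    n_whole = max(0, n_lateral - n_mosaic)
    kinds = (["mosaic"] * n_mosaic + ["whole"] * n_whole
             + ["vertical"] * (n - n_mosaic - n_whole))
    kinds = [kinds[i] for i in rng_fam.permutation(len(kinds))]
    moves = np.arange(1, len(config.spr_move_weights) + 1)
    L = config.alignment_codons * 3

    families = []
    for i, kind in enumerate(kinds):
        fam = f"F{i + 1:04d}"
        size = int(rng_fam.integers(config.family_size_min,
                                    min(config.family_size_max,
                                        config.n_strains) + 1))
        k = int(rng_fam.choice(moves, p=config.spr_move_weights))
        if kind == "vertical":
            tree, t_truth = simulate_gene_family(species, size, False, 0,
                                                 rng_fam)
            aln, a_truth = simulate_alignment([tree], L, config.divergence,
                                              (), rng_fam)
            truth = {"lgt_class": "vertical", "spr_moves": 0,
                     "breakpoints": []}
        elif kind == "whole":
            tree, t_truth = simulate_gene_family(species, size, True, k,
                                                 rng_fam)
            aln, a_truth = simulate_alignment([tree], L, config.divergence,
                                              (), rng_fam)
            truth = {"lgt_class": "whole_gene_lateral", "spr_moves": k,
                     "breakpoints": []}
        else:  # mosaic: concordant tree, within-gene transferred segment
            tree, t_truth = simulate_gene_family(species, size, False, 0,
                                                 rng_fam)
            donor = tree
            for _ in range(k):
                donor = random_spr(donor, rng_fam)
            lo, hi = int(0.3 * config.alignment_codons), \
                int(0.7 * config.alignment_codons)
            bp = 3 * int(rng_fam.integers(lo, hi + 1))
            aln, a_truth = simulate_alignment([tree, donor], L,
                                              config.divergence, [bp],
                                              rng_fam)
            truth = {"lgt_class": "within_gene_lateral", "spr_moves": k,
                     "breakpoints": [bp]}
        truth["taxa"] = t_truth["taxa"]
        families.append(FamilyData(fam, size, tree, aln, truth))

    trn, loci, tf_truth = simulate_trn(config, rng_trn)

    fam_ids = [f.family for f in families]
    tf_genes = sorted(trn.tf_set)
    replace = len(fam_ids) < len(tf_genes)
    picks = rng_map.choice(len(fam_ids), size=len(tf_genes), replace=replace)
    gene_family_map = {g: fam_ids[p] for g, p in zip(tf_genes, picks)}
    probs = np.array([0.25, 0.17, 0.15, 0.12, 0.11, 0.09, 0.06, 0.05])
    gene_categories = {}
    all_genes = sorted(set(loci))
    draws = rng_map.choice(len(_CATEGORIES), size=len(all_genes), p=probs)
    for g, d in zip(all_genes, draws):
        gene_categories[g] = _CATEGORIES[d]
    return Cohort(config, species, families, trn, loci, tf_truth,
                  gene_family_map, gene_categories)
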