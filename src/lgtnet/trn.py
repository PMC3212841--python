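"""Transcriptional regulatory network: construction and regulator classes.

The network is a directed gene -> gene graph: an edge runs from a
TF-encoding gene to each gene whose transcription the TF regulates.
Regulators fall into three classes: *global* (the k TFs with the most
targets, k=20 by default), *neighbour* (non-global TFs regulating a gene
immediately adjacent on the chromosome), and *other*.  A neighbour
regulator together with the maximal run of collinear adjacent targets it
regulates forms a *regulatory neighbourhood*.

Edge lists are read in the RegulonDB dialect: tab-separated
(regulator, target, effect, evidence), '#' comment lines skipped.
Heterodimeric TFs are expanded to one node per subunit-encoding gene, each
carrying the full target set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal placement of one gene; ``rank`` is its 0-based position
    in gene order along its replicon (assigned by the loci loader)."""

    gene: str
    replicon: str
    start: int
    end: int
    strand: str
    rank: int = -1


@dataclass
class RegulatoryNeighbourhood:
    """A neighbour TF plus the maximal collinear run of adjacent targets."""

    tf: str
    targets: list
    genes: list  # contiguous run in chromosome order, TF included

    @property
    def size(self) -> int:
        return len(self.genes)


class RegulatoryNetwork:
    """Directed TF-gene graph with optional heterodimer group annotations."""

    def __init__(self, heterodimer_groups=()):
        self.graph = nx.DiGraph()
        self.heterodimer_groups = [frozenset(g) for g in heterodimer_groups]
        self.skipped: list = []
        self._betweenness: dict | None = None

    # -- construction ----------------------------------------------------
    def add_edge(self, regulator: str, target: str) -> None:
        self.graph.add_edge(regulator, target)
        self._betweenness = None

    # -- basic queries ----------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def tf_set(self) -> set:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) > 0}

    def targets_of(self, tf: str) -> set:
        return set(self.graph.successors(tf))

    def out_degree(self, node: str) -> int:
        if node not in self.graph:
            raise KeyError(f"unknown gene {node!r}")
        return self.graph.out_degree(node)

    def betweenness(self, node: str) -> float:
        if node not in self.graph:
            raise KeyError(f"unknown gene {node!r}")
        if self._betweenness is None:
            self._betweenness = nx.betweenness_centrality(
                self.graph, normalized=False)
        return self._betweenness[node]

    def heterodimer_partners(self, gene: str) -> set:
        out = set()
        for grp in self.heterodimer_groups:
            if gene in grp:
                out |= grp - {gene}
        return out


def _read_edge_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     dtype=str, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["regulator", "target"]
    return df


def build_trn(tf_gene_path, tf_tf_path=None, exclusion=(),
              subunit_map=None) -> RegulatoryNetwork:
    """Build the network from RegulonDB-dialect edge files.

    ``exclusion`` lists genes (RNA genes, obsolete entries) whose edges are
    dropped; dropped rows are recorded in ``net.skipped``.  ``subunit_map``
    maps a heterodimeric regulator name to the genes encoding its subunits;
    each subunit gene receives the full target set and the genes are
    recorded as a heterodimer group.
    """
    subunit_map = dict(subunit_map or {})
    exclusion = set(exclusion)
    net = RegulatoryNetwork(
        heterodimer_groups=[frozenset(v) for v in subunit_map.values()
                            if len(v) > 1])
    frames = [_read_edge_tsv(tf_gene_path)]
    if tf_tf_path is not None:
        frames.append(_read_edge_tsv(tf_tf_path))
    for df in frames:
        for reg, tgt in df.itertuples(index=False):
            if not isinstance(reg, str) or not isinstance(tgt, str):
                net.skipped.append((reg, tgt, "unmappable"))
                continue
            reg, tgt = reg.strip(), tgt.strip()
            if not reg or not tgt:
                net.skipped.append((reg, tgt, "unmappable"))
                continue
            reg_genes = subunit_map.get(reg, [reg])
            if tgt in exclusion:
                net.skipped.append((reg, tgt, "excluded target"))
                continue
            for g in reg_genes:
                if g in exclusion:
                    net.skipped.append((g, tgt, "excluded regulator"))
                    continue
                net.add_edge(g, tgt)
    return net


def read_loci(path) -> dict:
    """Load a loci TSV (gene, replicon, start, end, strand) and assign
    chromosome ranks by start coordinate within each replicon."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene", "replicon", "start", "end", "strand"],
                     dtype={"gene": str, "replicon": str, "strand": str})
    out = {}
    for rep, sub in df.groupby("replicon"):
        sub = sub.sort_values("start").reset_index(drop=True)
        for rank, row in sub.iterrows():
            out[row.gene] = GeneLocus(row.gene, rep, int(row.start),
                                      int(row.end), row.strand, int(rank))
    return out


def _replicon_sizes(loci: dict) -> dict:
    sizes: dict = {}
    for loc in loci.values():
        sizes[loc.replicon] = max(sizes.get(loc.replicon, 0), loc.rank + 1)
    return sizes


def _rank_distance(a: GeneLocus, b: GeneLocus, sizes: dict) -> int | None:
    """Circular rank distance; None when on different replicons."""
    if a.replicon != b.replicon:
        return None
    n = sizes[a.replicon]
    d = abs(a.rank - b.rank)
    return min(d, n - d)


def classify_global(net: RegulatoryNetwork, k: int = 20) -> set:
    """The k regulator *units* with the largest target sets, as genes.

    Heterodimer subunit genes carrying an identical target set count as one
    unit, so the returned gene set can exceed k.  Units tied with the k-th
    are all included, with a warning.
    """
    tfs = net.tf_set
    # group heterodimer subunits with identical target sets into units
    units: list[tuple[frozenset, int]] = []
    assigned = set()
    for tf in sorted(tfs):
        if tf in assigned:
            continue
        unit = {tf}
        for p in net.heterodimer_partners(tf):
            if p in tfs and net.targets_of(p) == net.targets_of(tf):
                unit.add(p)
        assigned |= unit
        units.append((frozenset(unit), net.out_degree(tf)))
    if k > len(units):
        raise ValueError(f"k={k} exceeds the {len(units)} regulator units")
    units.sort(key=lambda u: (-u[1], sorted(u[0])))
    cutoff = units[k - 1][1]
    chosen = [u for u in units[:k]]
    tied = [u for u in units[k:] if u[1] == cutoff]
    if tied:
        warnings.warn(f"out-degree tie at rank {k}: including "
                      f"{sum(len(u[0]) for u in tied)} extra gene(s)")
        chosen += tied
    return set().union(*(u[0] for u in chosen))


def find_neighbour_regulators(net: RegulatoryNetwork, loci: dict,
                              global_set=()) -> set:
    """Non-global TFs regulating >= 1 target immediately adjacent (rank +-1,
    circular) on the chromosome.

    Self-regulation never counts as adjacency, and adjacent heterodimer
    subunits that regulate each other but no other adjacent gene are
    excluded.  TFs without a locus are skipped with a warning.
    """
    sizes = _replicon_sizes(loci)
    global_set = set(global_set)
    out = set()
    for tf in sorted(net.tf_set - global_set):
        if tf not in loci:
            warnings.warn(f"TF {tf!r} has no locus; skipped")
            continue
        tl = loci[tf]
        adjacent = set()
        for tgt in net.targets_of(tf):
            if tgt == tf or tgt not in loci:
                continue
            if _rank_distance(tl, loci[tgt], sizes) == 1:
                adjacent.add(tgt)
        if not adjacent:
            continue
        partners = net.heterodimer_partners(tf)
        if adjacent <= partners:
            continue  # heterodimer pair regulating only each other
        out.add(tf)
    return out


def extract_neighbourhood(net: RegulatoryNetwork, loci: dict,
                          tf: str) -> RegulatoryNeighbourhood:
    """Maximal contiguous run of rank-adjacent targets around a neighbour
    TF (either side), plus the TF itself."""
    sizes = _replicon_sizes(loci)
    tl = loci[tf]
    n = sizes[tl.replicon]
    by_rank = {loc.rank: g for g, loc in loci.items()
               if loc.replicon == tl.replicon}
    targets = net.targets_of(tf)

    def walk(direction: int) -> list:
        run = []
        r = tl.rank
        for _ in range(n - 1):
            r = (r + direction) % n
            g = by_rank.get(r)
            if g is None or g == tf or g not in targets:
                break
            run.append(g)
        return run

    down, up = walk(-1), walk(+1)
    genes = list(reversed(down)) + [tf] + up
    return RegulatoryNeighbourhood(tf=tf, targets=list(reversed(down)) + up,
                                   genes=genes)
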