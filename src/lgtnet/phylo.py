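"""Unrooted leaf-labelled trees with per-edge posterior supports.

The unit of analysis is an unrooted tree over a set of strain identifiers,
carrying a posterior probability (PP) on each internal edge.  Gene trees are
compared against a clade reference tree through their bipartitions (splits):
support-aware collapsing, pruning to a shared taxon set, and pairwise split
compatibility are the primitives everything downstream builds on.

Newick I/O is delegated to dendropy; supports are read from (and written as)
internal node labels, the convention used by Bayesian tree samplers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy


class NewickError(ValueError):
    """Malformed newick input; message includes the offending offset when known."""


def splits_compatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    """True iff splits ``a|taxa-a`` and ``b|taxa-b`` can coexist in one tree."""
    return a <= b or b <= a or a.isdisjoint(b) or (a | b) == taxa


@dataclass(frozen=True)
class Bipartition:
    """One non-trivial split of a taxon set, with the PP of the inducing edge."""

    side: frozenset
    taxa: frozenset
    support: float | None = None

    def __post_init__(self):
        if not self.side or self.side == self.taxa:
            raise ValueError("bipartition sides must both be non-empty")

    @property
    def other_side(self) -> frozenset:
        return self.taxa - self.side

    def is_trivial(self) -> bool:
        return min(len(self.side), len(self.taxa) - len(self.side)) < 2

    def compatible_with(self, other: "Bipartition") -> bool:
        return splits_compatible(self.side, other.side, self.taxa)


class PhyloTree:
    """Unrooted (optionally rooted) tree; nodes are opaque ints, leaves labelled.

    Edge attributes: ``length`` (branch length or None) and ``support``
    (posterior probability in [0, 1], or None meaning "not annotated",
    which all support-aware operations treat as fully supported).
    """

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._label: dict[int, str] = {}
        self._node_of: dict[str, int] = {}
        self._length: dict[frozenset, float | None] = {}
        self._support: dict[frozenset, float | None] = {}
        self._next = 0
        self.root: int | None = None

    # -- construction ------------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        v = self._next
        self._next += 1
        self._adj[v] = set()
        if label is not None:
            if label in self._node_of:
                raise NewickError(f"duplicate leaf label {label!r}")
            self._label[v] = label
            self._node_of[label] = v
        return v

    def add_edge(self, u: int, v: int, length: float | None = None,
                 support: float | None = None) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)
        e = frozenset((u, v))
        self._length[e] = length
        self._support[e] = support

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        e = frozenset((u, v))
        self._length.pop(e, None)
        self._support.pop(e, None)

    def remove_node(self, v: int) -> None:
        for u in list(self._adj[v]):
            self.remove_edge(u, v)
        del self._adj[v]
        lab = self._label.pop(v, None)
        if lab is not None:
            del self._node_of[lab]
        if self.root == v:
            self.root = None

    # -- basic queries -----------------------------------------------------
    @property
    def leaves(self) -> frozenset:
        return frozenset(self._node_of)

    @property
    def n_leaves(self) -> int:
        return len(self._label)

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def label_of(self, v: int) -> str:
        return self._label[v]

    def node_of(self, label: str) -> int:
        return self._node_of[label]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def nodes(self) -> Iterator[int]:
        return iter(self._adj)

    def neighbours(self, v: int) -> frozenset:
        return frozenset(self._adj[v])

    def edges(self) -> list[frozenset]:
        return list(self._length)

    def internal_edges(self) -> list[frozenset]:
        return [e for e in self._length
                if all(not self.is_leaf(v) for v in e)]

    def edge_length(self, u: int, v: int) -> float | None:
        return self._length[frozenset((u, v))]

    def edge_support(self, u: int, v: int) -> float | None:
        return self._support[frozenset((u, v))]

    def set_edge_length(self, u: int, v: int, x: float | None) -> None:
        self._length[frozenset((u, v))] = x

    def set_edge_support(self, u: int, v: int, x: float | None) -> None:
        self._support[frozenset((u, v))] = x

    def is_binary(self) -> bool:
        """All internal vertices of the unrooted tree have degree three."""
        return all(self.degree(v) == 3 for v in self._adj if not self.is_leaf(v)
                   and v != self.root)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {v: set(nb) for v, nb in self._adj.items()}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._length = dict(self._length)
        t._support = dict(self._support)
        t._next = self._next
        t.root = self.root
        return t

    # -- splits --------------------------------------------------------------
    def _below(self, parent: int, child: int) -> frozenset:
        """Leaf labels in the component containing ``child`` after cutting
        the (parent, child) edge."""
        seen = {parent, child}
        stack = [child]
        out = []
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(self._label[v])
            for u in self._adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return frozenset(out)

    def edge_split_sides(self) -> dict[frozenset, frozenset]:
        """Map every edge to the leaf set on an arbitrary-but-fixed side."""
        out = {}
        for e in self._length:
            u, v = tuple(e)
            out[e] = self._below(u, v)
        return out

    def splits(self, min_support: float | None = None,
               include_trivial: bool = False) -> dict[frozenset, float | None]:
        """Canonical split -> support.  Canonical side excludes the
        lexicographically smallest leaf label.  Only resolved internal edges
        produce non-trivial splits."""
        taxa = self.leaves
        if not taxa:
            return {}
        ref = min(taxa)
        out: dict[frozenset, float | None] = {}
        for e, side in self.edge_split_sides().items():
            if ref in side:
                side = taxa - side
            trivial = min(len(side), len(taxa) - len(side)) < 2
            if trivial and not include_trivial:
                continue
            sup = self._support[e]
            if min_support is not None and (sup is not None and sup < min_support):
                continue
            prev = out.get(side)
            if prev is None or (sup is not None and (prev is None or sup > prev)):
                out[side] = sup
        return out

    def bipartitions(self, min_support: float | None = None) -> list[Bipartition]:
        taxa = self.leaves
        return [Bipartition(side, taxa, sup)
                for side, sup in self.splits(min_support=min_support).items()]

    def topology_key(self) -> frozenset:
        """Label-based canonical topology identity (non-trivial splits only)."""
        return frozenset(self.splits())

    # -- surgery -------------------------------------------------------------
    def _suppress_degree2(self, v: int) -> None:
        if self.is_leaf(v) or self.degree(v) != 2:
            return
        a, b = tuple(self._adj[v])
        la, lb = self.edge_length(a, v), self.edge_length(b, v)
        sa, sb = self.edge_support(a, v), self.edge_support(b, v)
        length = None if (la is None and lb is None) else (la or 0.0) + (lb or 0.0)
        sups = [s for s in (sa, sb) if s is not None]
        support = min(sups) if sups else None
        self.remove_node(v)
        if b not in self._adj[a]:
            self.add_edge(a, b, length=length, support=support)

    def unroot(self) -> "PhyloTree":
        t = self.copy()
        r = t.root
        t.root = None
        if r is not None and r in t._adj and not t.is_leaf(r) and t.degree(r) == 2:
            t._suppress_degree2(r)
        return t

    def restrict(self, labels: Iterable[str]) -> "PhyloTree":
        """Prune to the given leaf set; suppress resulting degree-2 vertices."""
        keep = set(labels)
        missing = keep - set(self._node_of)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        t = self.unroot()
        drop = [t._node_of[l] for l in t._node_of if l not in keep]
        stack = list(drop)
        while stack:
            v = stack.pop()
            if v not in t._adj:
                continue
            nbs = list(t._adj[v])
            t.remove_node(v)
            for u in nbs:
                if u in t._adj and not t.is_leaf(u) and t.degree(u) <= 1:
                    stack.append(u)
        for v in list(t._adj):
            if v in t._adj and not t.is_leaf(v):
                t._suppress_degree2(v)
        return t

    def collapse_low_support(self, threshold: float) -> "PhyloTree":
        """Contract internal edges with support < threshold (inclusive keep).

        Unannotated edges (support None) are treated as fully supported.
        """
        if not 0.0 < threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        t = self.unroot()
        for e in t.internal_edges():
            if e not in t._length:
                continue
            sup = t._support[e]
            if sup is not None and sup < threshold:
                u, v = tuple(e)
                # contract: merge v into u
                for w in list(t._adj[v]):
                    if w == u:
                        continue
                    lw = t.edge_length(v, w)
                    sw = t.edge_support(v, w)
                    t.remove_edge(v, w)
                    t.add_edge(u, w, length=lw, support=sw)
                t.remove_node(v)
        return t

    # -- newick ---------------------------------------------------------------
    def _min_leaf_below(self, parent: int, child: int, cache: dict) -> str:
        key = (parent, child)
        if key not in cache:
            cache[key] = min(self._below(parent, child))
        return cache[key]

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        if self.n_leaves == 0:
            raise ValueError("empty tree")
        if self.n_leaves == 1:
            (lab,) = self.leaves
            return f"{lab};"
        cache: dict = {}

        def fmt_edge(parent: int, child: int) -> str:
            s = render(parent, child)
            sup = self.edge_support(parent, child)
            ln = self.edge_length(parent, child)
            if supports and sup is not None and not self.is_leaf(child):
                s += f"{sup:g}"
            if lengths and ln is not None:
                s += f":{ln:g}"
            return s

        def render(parent: int, child: int) -> str:
            if self.is_leaf(child):
                return self._label[child]
            kids = sorted((u for u in self._adj[child] if u != parent),
                          key=lambda u: self._min_leaf_below(child, u, cache))
            return "(" + ",".join(fmt_edge(child, u) for u in kids) + ")"

        if self.root is not None:
            start = self.root
        else:
            # print from the neighbour of the smallest leaf, so that the
            # basal multifurcation is at an internal vertex
            v0 = self._node_of[min(self.leaves)]
            start = next(iter(self._adj[v0])) if self.degree(v0) else v0
        kids = sorted(self._adj[start],
                      key=lambda u: self._min_leaf_below(start, u, cache))
        return "(" + ",".join(fmt_edge(start, u) for u in kids) + ");"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree n={self.n_leaves} {self.to_newick(lengths=False)}>"


# -- parsing -------------------------------------------------------------------

def _prescan(s: str) -> None:
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickError(
            f"unbalanced '(': {depth} unclosed at character offset {len(s)}")
    if ";" not in s:
        raise NewickError(f"missing ';' terminator at character offset {len(s)}")


def _from_dendropy(dt: "dendropy.Tree") -> PhyloTree:
    t = PhyloTree()
    node_map: dict = {}
    for nd in dt.preorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise NewickError("leaf without a label")
            v = t.add_node(str(lab))
        else:
            v = t.add_node()
        node_map[id(nd)] = v
        if nd.parent_node is not None:
            support = None
            if not nd.is_leaf():
                raw = nd.label
                if raw is not None:
                    try:
                        support = float(raw)
                    except ValueError:
                        support = None
            t.add_edge(node_map[id(nd.parent_node)], v,
                       length=nd.edge.length, support=support)
    # unrooted convention: suppress a degree-2 basal vertex
    seed = node_map[id(dt.seed_node)]
    if not t.is_leaf(seed) and t.degree(seed) == 2:
        t._suppress_degree2(seed)
    return t


def parse_newick(s: str) -> PhyloTree:
    _prescan(s)
    try:
        dt = dendropy.Tree.get(data=s, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
    except NewickError:
        raise
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failed: {exc}") from exc
    return _from_dendropy(dt)


def read_newick(path) -> list[PhyloTree]:
    """Read one tree per newick statement from a file."""
    with open(path) as fh:
        text = fh.read()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    if not trees:
        raise NewickError(f"no trees found in {path}")
    return trees


def write_newick(trees: "PhyloTree | Sequence[PhyloTree]", path) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# -- rooting ---------------------------------------------------------------------

def root_tree(tree: PhyloTree, outgroup: "str | Iterable[str]") -> PhyloTree:
    """Root on the edge whose split separates ``outgroup`` from the rest.

    ``outgroup`` is a single leaf label or a set of labels that must form one
    side of an existing edge; otherwise (non-monophyletic spec) an error is
    raised.  The unrooted bipartition set is unchanged.
    """
    if isinstance(outgroup, str):
        side = frozenset([outgroup])
    else:
        side = frozenset(outgroup)
    taxa = tree.leaves
    if not side or not side <= taxa:
        raise ValueError("outgroup labels must be a non-empty subset of the leaves")
    t = tree.unroot()
    target = None
    for e, below in t.edge_split_sides().items():
        if below == side or (taxa - below) == side:
            target = e
            break
    if target is None:
        raise ValueError(f"outgroup {sorted(side)} does not match any edge "
                         "(not monophyletic in this tree)")
    u, v = tuple(target)
    length = t._length[target]
    support = t._support[target]
    t.remove_edge(u, v)
    r = t.add_node()
    half = None if length is None else length / 2.0
    t.add_edge(r, u, length=half, support=support)
    t.add_edge(r, v, length=half, support=support)
    t.root = r
    return t


# -- discordance -------------------------------------------------------------------

def is_discordant(test: PhyloTree, reference: PhyloTree,
                  threshold: float = 0.95) -> bool:
    """Support-aware topological conflict between a gene tree and the reference.

    The reference is pruned to the test taxon set; the test tree is collapsed
    at the PP threshold (inclusive: edges at exactly the threshold are kept).
    The pair is discordant iff some resolved, retained test split is
    incompatible with a split of the pruned reference.  Polytomies left by
    collapsing count as uncertainty, never as conflict.
    """
    shared = test.leaves & reference.leaves
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared taxa for a discordance call, got {len(shared)}")
    t = test.restrict(shared).collapse_low_support(threshold)
    r = reference.restrict(shared)
    ref_splits = list(r.splits())
    taxa = frozenset(shared)
    for side in t.splits():
        for rs in ref_splits:
            if not splits_compatible(side, rs, taxa):
                return True
    return False
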