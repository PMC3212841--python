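"""Subtree prune-and-regraft (SPR) operations and edit distance.

A single SPR move cuts an edge of an unrooted binary tree and regrafts the
detached subtree onto another edge of the remainder.  The *edit distance*
between a gene tree and the reference is the minimum number of SPR moves
reconciling them; each move is interpreted as one transfer event.

Computing this distance is NP-hard, so the search is budgeted: trees are
first reduced by collapsing shared pendant subtrees (distance-preserving),
then explored with a bidirectional breadth-first search over SPR
neighbourhoods up to ``d_max`` moves.  Searches exceeding the budget report
UNRESOLVED rather than an approximate value.

The search operates on a compact integer representation: leaves are bits in
a mask, a topology is the frozenset of its canonical non-trivial splits.
"""
from __future__ import annotations

from dataclasses import dataclass

from .phylo import PhyloTree, splits_compatible

Adj = dict  # node id -> set of node ids; leaves are 0..n-1


@dataclass(frozen=True)
class EditResult:
    """Outcome of an SPR distance search."""

    distance: int | None  # None <=> UNRESOLVED
    d_max: int

    @property
    def unresolved(self) -> bool:
        return self.distance is None


# -- internal integer-leaf representation ---------------------------------------

def _to_adj(tree: PhyloTree, order: list[str]) -> Adj:
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    remap: dict[int, int] = {}
    nxt = n
    for v in tree.nodes():
        if tree.is_leaf(v):
            remap[v] = idx[tree.label_of(v)]
        else:
            remap[v] = nxt
            nxt += 1
    adj: Adj = {remap[v]: set() for v in tree.nodes()}
    for e in tree.edges():
        u, v = tuple(e)
        adj[remap[u]].add(remap[v])
        adj[remap[v]].add(remap[u])
    return adj


def _splits_key(adj: Adj, n: int) -> frozenset:
    """Canonical topology key: frozenset of non-trivial split masks, each
    taken on the side not containing leaf 0."""
    full = (1 << n) - 1
    root = next(iter(adj[0]))  # neighbour of leaf 0
    masks = []
    # iterative postorder from root with parent = leaf 0
    stack = [(root, 0, False)]
    below: dict[tuple, int] = {}
    while stack:
        v, parent, done = stack.pop()
        if v < n:
            below[(parent, v)] = 1 << v
            continue
        if not done:
            stack.append((v, parent, True))
            for u in adj[v]:
                if u != parent:
                    stack.append((u, v, False))
        else:
            m = 0
            for u in adj[v]:
                if u != parent:
                    m |= below[(v, u)]
            below[(parent, v)] = m
            if m & 1:
                m ^= full
            c = bin(m).count("1")
            if 2 <= c <= n - 2:
                masks.append(m)
    return frozenset(masks)


def _spr_neighbours(adj: Adj, n: int):
    """Yield adjacency maps of all trees one SPR move away (binary input)."""
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    for a, b in edges:
        for u, v in ((a, b), (b, a)):
            # prune the component containing v by cutting (u, v)
            if u < n:  # leaf on the kept side: nothing to regraft onto
                continue
            x, y = (w for w in adj[u] if w != v)  # u suppressed -> origin edge (x,y)
            # collect edges of the remaining component (excluding u)
            rem_edges = []
            seen = {u, v}
            stack = [x, y]
            comp = set()
            while stack:
                w = stack.pop()
                if w in comp or w in seen:
                    continue
                comp.add(w)
                for z in adj[w]:
                    if z == u or z in seen:
                        continue
                    if z in comp:
                        rem_edges.append((w, z))
                    else:
                        stack.append(z)
            rem_edges.append((x, y))
            for p, q in rem_edges:
                if (p, q) in ((x, y), (y, x)):
                    continue  # regrafting onto the origin edge recreates the input
                new = {k: set(s) for k, s in adj.items()}
                # detach
                new[u].discard(v)
                new[v].discard(u)
                new[x].discard(u)
                new[y].discard(u)
                new[x].add(y)
                new[y].add(x)
                del new[u]
                # re-subdivide (p, q) with a fresh vertex (reuse id u)
                new[p].discard(q)
                new[q].discard(p)
                new[u] = {p, q, v}
                new[p].add(u)
                new[q].add(u)
                new[v].add(u)
                yield new


def _common_cherry_reduce(adj1: Adj, adj2: Adj, n: int) -> tuple[Adj, Adj, int]:
    """Iteratively collapse cherries shared by both trees (distance-preserving).

    Returns relabelled trees over a smaller leaf set 0..m-1.
    """
    def parent_of(adj, leaf):
        return next(iter(adj[leaf]))

    leaves = set(range(n))
    a1 = {k: set(s) for k, s in adj1.items()}
    a2 = {k: set(s) for k, s in adj2.items()}
    changed = True
    while changed and len(leaves) > 4:
        changed = False
        for x in sorted(leaves):
            p1 = parent_of(a1, x)
            sibs1 = {w for w in a1[p1] if w in leaves and w != x}
            if not sibs1:
                continue
            p2 = parent_of(a2, x)
            sibs2 = {w for w in a2[p2] if w in leaves and w != x}
            common = sibs1 & sibs2
            if not common:
                continue
            y = min(common)
            # drop y, suppress its (now degree-2) parents
            for adj in (a1, a2):
                p = parent_of(adj, y)
                adj[p].discard(y)
                del adj[y]
                if len(adj[p]) == 2:
                    r, s = tuple(adj[p])
                    adj[r].discard(p)
                    adj[s].discard(p)
                    adj[r].add(s)
                    adj[s].add(r)
                    del adj[p]
            leaves.discard(y)
            changed = True
            break
    # relabel leaves to 0..m-1 (internal ids shifted above m)
    m = len(leaves)
    lmap = {old: i for i, old in enumerate(sorted(leaves))}
    out = []
    for adj in (a1, a2):
        imap = dict(lmap)
        nxt = m
        for v in adj:
            if v not in imap:
                imap[v] = nxt
                nxt += 1
        out.append({imap[v]: {imap[w] for w in s} for v, s in adj.items()})
    return out[0], out[1], m


# -- polytomy handling -----------------------------------------------------------

def _try_insert_split(tree: PhyloTree, side: frozenset) -> bool:
    """Insert the split ``side | rest`` if compatible with the tree; in-place."""
    taxa = tree.leaves
    comp = taxa - side
    for v in list(tree.nodes()):
        if tree.is_leaf(v) or tree.degree(v) < 4:
            continue
        inside, outside = [], []
        ok = True
        for u in tree.neighbours(v):
            below = tree._below(v, u)
            if below <= side:
                inside.append(u)
            elif below <= comp:
                outside.append(u)
            else:
                ok = False
                break
        if ok and len(inside) >= 2 and len(outside) >= 2 and \
                frozenset().union(*(tree._below(v, u) for u in inside)) == side:
            w = tree.add_node()
            for u in inside:
                ln = tree.edge_length(v, u)
                sp = tree.edge_support(v, u)
                tree.remove_edge(v, u)
                tree.add_edge(w, u, length=ln, support=sp)
            tree.add_edge(v, w)
            return True
    return False


def resolve_polytomies(tree: PhyloTree,
                       guide: PhyloTree | None = None) -> PhyloTree:
    """Return a binary refinement: guide-compatible splits first, then a
    deterministic caterpillar-style resolution of whatever remains."""
    t = tree.copy()
    if guide is not None:
        own = set(t.splits())
        taxa = t.leaves
        for side in sorted(guide.splits(), key=lambda s: (len(s), sorted(s))):
            if side in own:
                continue
            if all(splits_compatible(side, s, taxa) for s in own):
                if _try_insert_split(t, side):
                    own.add(side)
    # deterministic fallback resolution
    again = True
    while again:
        again = False
        for v in list(t.nodes()):
            if not t.is_leaf(v) and t.degree(v) > 3:
                nbs = sorted(t.neighbours(v),
                             key=lambda u: min(t._below(v, u)))
                a, b = nbs[0], nbs[1]
                w = t.add_node()
                for u in (a, b):
                    ln = t.edge_length(v, u)
                    sp = t.edge_support(v, u)
                    t.remove_edge(v, u)
                    t.add_edge(w, u, length=ln, support=sp)
                t.add_edge(v, w)
                again = True
                break
    return t


# -- public operations --------------------------------------------------------

def spr_neighbours(tree: PhyloTree) -> list[PhyloTree]:
    """All topologies one SPR move from an unrooted binary tree (deduplicated).

    Branch lengths and supports are not carried over; this is a topology-level
    operation used by searches and by the synthetic-data generator.
    """
    if not tree.is_binary():
        raise ValueError("SPR neighbourhood requires a binary tree")
    order = sorted(tree.leaves)
    n = len(order)
    adj = _to_adj(tree.unroot(), order)
    seen = set()
    out = []
    for nadj in _spr_neighbours(adj, n):
        k = _splits_key(nadj, n)
        if k in seen:
            continue
        seen.add(k)
        out.append(_from_adj(nadj, order))
    return out


def _from_adj(adj: Adj, order: list[str]) -> PhyloTree:
    n = len(order)
    t = PhyloTree()
    remap = {}
    for v in sorted(adj):
        remap[v] = t.add_node(order[v] if v < n else None)
    done = set()
    for v, nbs in adj.items():
        for u in nbs:
            e = frozenset((u, v))
            if e not in done:
                done.add(e)
                t.add_edge(remap[u], remap[v])
    return t


def random_spr(tree: PhyloTree, rng) -> PhyloTree:
    """Apply one uniformly chosen non-identity SPR move, keeping branch
    lengths plausible (merged edges sum, subdivided edges halve)."""
    if not tree.is_binary():
        raise ValueError("SPR requires a binary tree")
    if tree.n_leaves < 4:
        raise ValueError("SPR requires >= 4 leaves")
    base_key = tree.topology_key()
    for _ in range(200):
        t = tree.unroot()
        edges = [(u, v) for e in t.edges() for u, v in (tuple(e), tuple(e)[::-1])]
        cands = [(u, v) for u, v in edges if not t.is_leaf(u)]
        u, v = cands[rng.integers(len(cands))]
        cut_len = t.edge_length(u, v)
        x, y = (w for w in t.neighbours(u) if w != v)
        lx, ly = t.edge_length(u, x), t.edge_length(u, y)
        t.remove_edge(u, v)
        t.remove_edge(u, x)
        t.remove_edge(u, y)
        t.remove_node(u)
        merged = None if (lx is None and ly is None) else (lx or 0.0) + (ly or 0.0)
        t.add_edge(x, y, length=merged)
        # remaining-component edges reachable from x
        comp = set()
        stack = [x]
        while stack:
            w = stack.pop()
            if w in comp:
                continue
            comp.add(w)
            stack.extend(t.neighbours(w))
        rem = [e for e in t.edges()
               if all(w in comp for w in e) and e != frozenset((x, y))]
        if not rem:
            continue
        p, q = tuple(rem[rng.integers(len(rem))])
        lpq = t.edge_length(p, q)
        t.remove_edge(p, q)
        w = t.add_node()
        half = None if lpq is None else lpq / 2.0
        t.add_edge(p, w, length=half)
        t.add_edge(q, w, length=half)
        t.add_edge(w, v, length=cut_len)
        if t.topology_key() != base_key:
            return t
    raise RuntimeError("could not find a non-identity SPR move")


def spr_edit_distance(test: PhyloTree, reference: PhyloTree,
                      d_max: int = 6, collapse_threshold: float | None = None,
                      budget: int = 300_000) -> EditResult:
    """Minimum number of SPR moves between two trees on their shared taxa.

    The test tree may be support-collapsed first (``collapse_threshold``);
    any polytomy is refined toward the reference before searching, so
    uncertainty never inflates the distance.  Exact up to ``d_max``;
    ``UNRESOLVED`` (distance None) when the answer exceeds ``d_max`` or the
    search exceeds its expansion ``budget``.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    shared = test.leaves & reference.leaves
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa, got {len(shared)}")
    t = test.restrict(shared)
    if collapse_threshold is not None:
        t = t.collapse_low_support(collapse_threshold)
    r = reference.restrict(shared)
    if not t.is_binary():
        t = resolve_polytomies(t, guide=r)
    if not r.is_binary():
        r = resolve_polytomies(r, guide=t)
    order = sorted(shared)
    n = len(order)
    a1 = _to_adj(t, order)
    a2 = _to_adj(r, order)
    if _splits_key(a1, n) == _splits_key(a2, n):
        return EditResult(0, d_max)
    a1, a2, n = _common_cherry_reduce(a1, a2, n)

    k1, k2 = _splits_key(a1, n), _splits_key(a2, n)
    if k1 == k2:
        return EditResult(0, d_max)
    seen = ({k1: 0}, {k2: 0})
    front = ({k1: a1}, {k2: a2})
    depth = [0, 0]
    best: int | None = None
    spent = 0
    while depth[0] + depth[1] < d_max:
        if best is not None and depth[0] + depth[1] + 1 >= best:
            break
        side = 0 if len(front[0]) <= len(front[1]) else 1
        other = 1 - side
        new_front: dict = {}
        for adj in front[side].values():
            for nadj in _spr_neighbours(adj, n):
                spent += 1
                if spent > budget:
                    return EditResult(best, d_max) if best is not None \
                        else EditResult(None, d_max)
                k = _splits_key(nadj, n)
                if k in seen[side]:
                    continue
                seen[side][k] = depth[side] + 1
                hit = seen[other].get(k)
                if hit is not None:
                    cand = depth[side] + 1 + hit
                    if best is None or cand < best:
                        best = cand
                new_front[k] = nadj
        front = (new_front, front[1]) if side == 0 else (front[0], new_front)
        depth[side] += 1
        if not new_front:
            break
    if best is not None and best <= d_max:
        return EditResult(best, d_max)
    return EditResult(None, d_max)
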