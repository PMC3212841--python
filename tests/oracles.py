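"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written against networkx graphs rather than
the package's own tree machinery: topology enumeration by leaf insertion,
splits by edge deletion + connected components, SPR neighbourhoods by
explicit prune/regraft surgery, parsimony by set-based Fitch recursion, and
exact 2x2 / rank-sum p-values by full enumeration.
"""
from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import networkx as nx
import numpy as np


def splits_key(G: nx.Graph, leaves) -> frozenset:
    """Canonical non-trivial splits of an unrooted tree graph."""
    leaves = frozenset(leaves)
    ref = min(leaves)
    out = set()
    for e in G.edges:
        H = G.copy()
        H.remove_edge(*e)
        comp = nx.node_connected_component(H, e[0])
        side = frozenset(l for l in leaves if l in comp)
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return frozenset(out)


def all_topologies(labels) -> list:
    """All unrooted binary topologies on the labels, as networkx graphs."""
    labels = list(labels)
    assert len(labels) >= 3
    base = nx.Graph()
    base.add_edges_from([("__i0", l) for l in labels[:3]])
    trees = [base]
    counter = 1
    for lab in labels[3:]:
        nxt = []
        for T in trees:
            for e in list(T.edges):
                H = T.copy()
                H.remove_edge(*e)
                mid = f"__i{counter}_{len(nxt)}"
                H.add_edges_from([(e[0], mid), (e[1], mid), (mid, lab)])
                nxt.append(H)
        trees = nxt
        counter += 1
    return trees


def spr_neighbours_nx(G: nx.Graph, leaves) -> list:
    """All trees one SPR move away (graphs; may contain duplicates)."""
    out = []
    for u, v in itertools.chain(G.edges, [(b, a) for a, b in G.edges]):
        # prune the side containing v; u stays in the remainder
        if G.degree(u) == 1:
            continue
        H = G.copy()
        H.remove_edge(u, v)
        keep = nx.node_connected_component(H, u)
        a, b = [w for w in H.neighbors(u)]
        H.remove_node(u)
        H.add_edge(a, b)
        for x, y in list(H.edges):
            if {x, y} <= keep and {x, y} != {a, b}:
                N = H.copy()
                N.remove_edge(x, y)
                N.add_edges_from([(x, u), (y, u), (u, v)])
                out.append(N)
    return out


def spr_distance_matrix(labels):
    """(key -> index, dense all-pairs SPR distance matrix) via BFS over the
    full SPR graph of the topology space."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import shortest_path

    trees = all_topologies(labels)
    keys = [splits_key(T, labels) for T in trees]
    index = {k: i for i, k in enumerate(keys)}
    A = lil_matrix((len(trees), len(trees)), dtype=np.int8)
    for i, T in enumerate(trees):
        for N in spr_neighbours_nx(T, labels):
            j = index[splits_key(N, labels)]
            if j != i:
                A[i, j] = 1
    D = shortest_path(A.tocsr(), method="D", unweighted=True, directed=False)
    return index, D


def fitch_length(G: nx.Graph, leaves, states: dict) -> int:
    """Parsimony length of one character; states maps leaf -> set of states."""
    root = next(iter(leaves))
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in G.neighbors(v):
            if w not in parent:
                parent[w] = v
                stack.append(w)
    cost = 0
    sets: dict = {}
    for v in reversed(order):
        kids = [w for w in G.neighbors(v) if parent.get(w) == v]
        if not kids:
            sets[v] = set(states[v])
            continue
        acc = sets[kids[0]] if v not in states else set(states[v])
        for w in kids if v in states else kids[1:]:
            inter = acc & sets[w]
            if inter:
                acc = inter
            else:
                acc = acc | sets[w]
                cost += 1
        sets[v] = acc
    return cost


def brute_force_parsimony(labels, columns):
    """Best score and the set of optimal topology keys by exhaustive search.

    ``columns`` are (ones, zeros) label-set pairs; absent labels are missing
    (= either state).
    """
    best = None
    best_keys = set()
    for T in all_topologies(labels):
        score = 0
        for ones, zeros in columns:
            states = {}
            for l in labels:
                states[l] = ({1} if l in ones else
                             {0} if l in zeros else {0, 1})
            score += fitch_length(T, labels, states)
        if best is None or score < best:
            best = score
            best_keys = {splits_key(T, labels)}
        elif score == best:
            best_keys.add(splits_key(T, labels))
    return best, best_keys


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def ranksum_two_sided(a, b) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    from scipy.stats import rankdata

    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = rankdata(pooled)
    n1, n = len(a), len(pooled)
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total
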