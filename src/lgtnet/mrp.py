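"""Matrix representation with parsimony (MRP) supertree construction.

Every adequately supported bipartition of every gene tree becomes one binary
character (1 = taxon on one side, 0 = other side, ? = taxon absent from that
family).  The reference tree is the most parsimonious tree over this matrix,
found here by seeded hill-climbing (stepwise addition + NNI/SPR
rearrangements with restarts) rather than an external parsimony program.

Fitch scoring packs all characters of a taxon into one Python integer,
two bits per character, so one tree evaluation is O(taxa) big-int operations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import PhyloTree
from .spr import _from_adj, _splits_key, _spr_neighbours, _to_adj


@dataclass
class MRPMatrix:
    """Taxa x harvested-bipartition character matrix with missing data."""

    taxa: list
    # one column per harvested split occurrence: (ones side, zeros side)
    columns: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def state(self, taxon: str, j: int) -> str:
        ones, zeros = self.columns[j]
        if taxon in ones:
            return "1"
        if taxon in zeros:
            return "0"
        return "?"

    def to_phylip(self) -> str:
        """Relaxed PHYLIP character block (taxon name, space, 0/1/? states)."""
        width = max(len(t) for t in self.taxa) + 2
        lines = [f"{len(self.taxa)} {self.n_columns}"]
        for t in self.taxa:
            row = "".join(self.state(t, j) for j in range(self.n_columns))
            lines.append(f"{t:<{width}}{row}")
        return "\n".join(lines) + "\n"

    def packed(self) -> dict:
        """taxon -> packed Fitch state sets (01=state 0, 10=state 1, 11=?)."""
        out = {}
        for t in self.taxa:
            acc = 0
            for j, (ones, zeros) in enumerate(self.columns):
                if t in ones:
                    bits = 0b10
                elif t in zeros:
                    bits = 0b01
                else:
                    bits = 0b11
                acc |= bits << (2 * j)
            out[t] = acc
        return out

    def all_missing_taxa(self) -> list:
        out = []
        for t in self.taxa:
            if all(t not in ones and t not in zeros for ones, zeros in self.columns):
                out.append(t)
        return out


def harvest_bipartitions(trees, pp_threshold: float = 0.95) -> MRPMatrix:
    """Aggregate all non-trivial splits with PP >= threshold across gene trees.

    Each qualifying split of each tree contributes its own character, so a
    split seen in several families is (deliberately) represented repeatedly.
    Taxa absent from a family are coded missing for that family's characters.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    if not 0.0 < pp_threshold <= 1.0:
        raise ValueError("pp_threshold must be in (0, 1]")
    taxa = sorted(set().union(*(t.leaves for t in trees)))
    cols = []
    for t in trees:
        lv = t.leaves
        for side, sup in t.splits().items():
            if sup is not None and sup < pp_threshold:
                continue
            cols.append((side, lv - side))
    return MRPMatrix(taxa=taxa, columns=cols)


# -- packed Fitch ----------------------------------------------------------------

def _fitch_combine(a: int, b: int, mask01: int, ncols: int):
    inter = a & b
    occ = (inter | (inter >> 1)) & mask01
    empty = ncols - occ.bit_count()
    if empty:
        z = mask01 & ~occ
        z |= z << 1
        return (inter & ~z) | ((a | b) & z), empty
    return inter, 0


def _fitch_score(adj: dict, n_present: int, states: list, mask01: int,
                 ncols: int) -> int:
    """Fitch parsimony length of a binary unrooted tree; leaves are
    0..n_present-1 indexing into ``states``."""
    if ncols == 0:
        return 0
    leaf0 = min(v for v in adj if v < n_present)
    root = next(iter(adj[leaf0]))
    score = 0
    stack = [(root, leaf0, False)]
    part: dict = {}
    while stack:
        v, parent, done = stack.pop()
        if v < n_present:
            part[(parent, v)] = states[v]
            continue
        if not done:
            stack.append((v, parent, True))
            for u in adj[v]:
                if u != parent:
                    stack.append((u, v, False))
        else:
            kids = [part.pop((v, u)) for u in adj[v] if u != parent]
            m = kids[0]
            for c in kids[1:]:
                m, extra = _fitch_combine(m, c, mask01, ncols)
                score += extra
            part[(parent, v)] = m
    m, extra = _fitch_combine(part[(leaf0, root)], states[leaf0], mask01, ncols)
    score += extra
    return score


def _nni_neighbours(adj: dict, n: int):
    """Yield the two NNI rearrangements of every internal edge."""
    internal = [(u, v) for u in adj for v in adj[u]
                if u < v and u >= n and v >= n]
    for u, v in internal:
        a, b = (w for w in adj[u] if w != v)
        c, d = (w for w in adj[v] if w != u)
        for x, y in ((b, c), (b, d)):
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(x)
            new[v].discard(y)
            new[x].discard(u)
            new[y].discard(v)
            new[u].add(y)
            new[y].add(u)
            new[v].add(x)
            new[x].add(v)
            yield new


def build_mrp_supertree(matrix: MRPMatrix, seed: int = 0,
                        n_restarts: int = 10) -> PhyloTree:
    """Heuristic maximum-parsimony tree over an MRP matrix.

    Seeded random-addition starting trees refined by steepest-ascent NNI with
    an SPR kick when NNI stalls; ``n_restarts`` independent starts.  The
    search stops early when a tree attains the theoretical minimum length
    (one change per informative character).  Ties between equally
    parsimonious trees are broken by the lexicographically smallest newick
    string, so the result is deterministic given the seed.
    """
    taxa = list(matrix.taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa for a supertree")
    missing = matrix.all_missing_taxa()
    if missing:
        raise ValueError(f"taxa with no character data: {missing}")
    ncols = matrix.n_columns
    mask01 = int("01" * ncols, 2) if ncols else 0
    packed = matrix.packed()
    order_all = sorted(taxa)
    states = [packed[t] for t in order_all]
    rng = np.random.default_rng(seed)
    lower_bound = ncols  # every two-state character needs >= 1 change

    def score(adj):
        return _fitch_score(adj, n, states, mask01, ncols)

    best_adj = None
    best_score = None
    best_key = None
    for _ in range(max(1, n_restarts)):
        addition = list(rng.permutation(n))
        # seed 3-leaf star
        adj = {addition[0]: {n}, addition[1]: {n}, addition[2]: {n},
               n: set(addition[:3])}
        nxt = n + 1
        for leaf in addition[3:]:
            edges = sorted((tuple(sorted((u, v))) for u in adj for v in adj[u]
                            if u < v))
            cand_best = None
            for u, v in edges:
                adj[u].discard(v)
                adj[v].discard(u)
                adj[nxt] = {u, v, leaf}
                adj[u].add(nxt)
                adj[v].add(nxt)
                adj[leaf] = {nxt}
                s = score(adj)
                if cand_best is None or s < cand_best[0]:
                    cand_best = (s, u, v)
                # undo
                del adj[nxt]
                del adj[leaf]
                adj[u].discard(nxt)
                adj[v].discard(nxt)
                adj[u].add(v)
                adj[v].add(u)
            _, u, v = cand_best
            adj[u].discard(v)
            adj[v].discard(u)
            adj[nxt] = {u, v, leaf}
            adj[u].add(nxt)
            adj[v].add(nxt)
            adj[leaf] = {nxt}
            nxt += 1
        cur = score(adj)
        # hill climb: steepest-ascent NNI, SPR kick on stall
        improved = True
        while improved and cur > lower_bound:
            improved = False
            move_best = None
            for nadj in _nni_neighbours(adj, n):
                s = score(nadj)
                if s < cur and (move_best is None or s < move_best[0]):
                    move_best = (s, nadj)
            if move_best is None:
                for nadj in _spr_neighbours(adj, n):
                    s = score(nadj)
                    if s < cur and (move_best is None or s < move_best[0]):
                        move_best = (s, nadj)
            if move_best is not None:
                cur, adj = move_best
                improved = True
        key = None
        if best_score is None or cur < best_score:
            best_score, best_adj = cur, adj
            best_key = _from_adj(adj, order_all).to_newick(lengths=False)
        elif cur == best_score:
            key = _from_adj(adj, order_all).to_newick(lengths=False)
            if key < best_key:
                best_adj, best_key = adj, key
        if best_score <= lower_bound:
            break
    return _from_adj(best_adj, order_all)
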