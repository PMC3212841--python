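"""Phase-2 breakpoint detection: change-point segmentation over topologies.

Gene sets passing the phase-1 screen are segmented by a penalized dynamic
program: every candidate topology gets a per-site log-likelihood profile
under a single-parameter (Jukes-Cantor) substitution model, and the program
finds the site-segmentation maximizing total log-likelihood minus
``penalty`` per topology switch.  Breakpoints are reported where the
selected topology changes; flanking-segment support (softmax likelihood
weight of the chosen topology within the segment) grades each call into
evidence classes A/B/C.

A gene set is ORB+ (observable recombination breakpoint positive) when the
screen passed *and* segmentation yields a class A/B/C breakpoint; everything
else is ORB-.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .phylo import PhyloTree, parse_newick, splits_compatible
from .screen import ScreenResult, _encode

_CLASS_ORDER = {"A": 0, "B": 1, "C": 2, "none": 3}


@dataclass
class BreakpointCall:
    """Segmentation result for one gene set.

    ``positions`` are 0-based alignment columns marking the left edge of each
    right-hand segment (half-open boundaries); ``segment_topologies`` holds
    one candidate index per segment; ``segment_supports`` the softmax
    likelihood weight of the chosen topology within each segment.
    """

    positions: list
    segment_topologies: list
    segment_supports: list
    candidates: list = field(default_factory=list, repr=False)
    evidence_class: str = "none"

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("breakpoint positions must be strictly increasing")
        if len(self.segment_topologies) != len(self.positions) + 1:
            raise ValueError("segments must equal breakpoints + 1")

    def original_positions(self, column_map) -> list:
        return [int(column_map[p]) for p in self.positions]


def site_log_likelihoods(aln: Alignment, trees, default_branch: float = 0.05
                         ) -> np.ndarray:
    """(n_trees, L) per-site log-likelihoods under Jukes-Cantor.

    Branch lengths come from the trees where present (clamped to
    [1e-4, 5.0]); otherwise ``default_branch`` is used.  Gaps and ambiguous
    bases contribute a flat partial likelihood.
    """
    codes = _encode(aln)
    names = list(aln.sequences)
    L = aln.length
    out = np.empty((len(trees), L))
    for ti, tree in enumerate(trees):
        t = tree.restrict(set(names) & tree.leaves)
        if t.leaves != frozenset(names):
            raise ValueError("candidate tree does not cover alignment taxa")
        root = next(v for v in t.nodes() if not t.is_leaf(v))
        partials: dict = {}
        stack = [(root, None, False)]
        while stack:
            v, parent, done = stack.pop()
            if t.is_leaf(v):
                row = codes[names.index(t.label_of(v))]
                P = np.zeros((L, 4))
                ok = row != 255
                P[ok, row[ok]] = 1.0
                P[~ok] = 1.0
                partials[v] = P
                continue
            if not done:
                stack.append((v, parent, True))
                for u in t.neighbours(v):
                    if u != parent:
                        stack.append((u, v, False))
            else:
                acc = np.ones((L, 4))
                for u in t.neighbours(v):
                    if u == parent:
                        continue
                    bl = t.edge_length(v, u)
                    bl = default_branch if bl is None else min(max(bl, 1e-4), 5.0)
                    e = np.exp(-4.0 * bl / 3.0)
                    same, diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
                    M = np.full((4, 4), diff)
                    np.fill_diagonal(M, same)
                    acc *= partials.pop(u) @ M
                partials[v] = acc
        out[ti] = np.log(np.maximum(partials[root].mean(axis=1), 1e-300))
    return out


def _dedupe(trees) -> list:
    seen, out = set(), []
    for t in trees:
        k = t.topology_key()
        if k not in seen:
            seen.add(k)
            out.append(t)
    return out


def segment_alignment(aln: Alignment, candidate_topologies,
                      penalty: float = 25.0,
                      default_branch: float = 0.05) -> BreakpointCall:
    """Penalized maximum-likelihood segmentation of an alignment.

    Finds the per-site assignment of candidate topologies maximizing
    total log-likelihood minus ``penalty`` per topology switch; a switch is
    reported only when it buys more than the penalty in likelihood, so
    ``penalty -> inf`` always yields a single segment.
    """
    cands = _dedupe(list(candidate_topologies))
    if not cands:
        raise ValueError("empty candidate topology set")
    ll = site_log_likelihoods(aln, cands, default_branch=default_branch)
    K, L = ll.shape
    if K == 1:
        seg_sup = [1.0]
        return BreakpointCall([], [0], seg_sup, candidates=cands)
    dp = ll[:, 0].copy()
    back = np.zeros((L, K), dtype=np.int32)
    back[0] = np.arange(K)
    for i in range(1, L):
        best_j = int(np.argmax(dp))
        switch = dp[best_j] - penalty
        stay = dp
        new = np.where(stay >= switch, stay, switch) + ll[:, i]
        back[i] = np.where(stay >= switch, np.arange(K), best_j)
        dp = new
    labels = np.empty(L, dtype=np.int32)
    labels[-1] = int(np.argmax(dp))
    for i in range(L - 1, 0, -1):
        labels[i - 1] = back[i][labels[i]]
    positions = [int(i) for i in np.flatnonzero(np.diff(labels)) + 1]
    bounds = [0] + positions + [L]
    seg_topo, seg_sup = [], []
    for s, e in zip(bounds[:-1], bounds[1:]):
        k = int(labels[s])
        tot = ll[:, s:e].sum(axis=1)
        w = np.exp(tot - tot.max())
        seg_topo.append(k)
        seg_sup.append(float(w[k] / w.sum()))
    return BreakpointCall(positions, seg_topo, seg_sup, candidates=cands)


def _trees_incompatible(t1: PhyloTree, t2: PhyloTree) -> bool:
    shared = t1.leaves & t2.leaves
    if len(shared) < 4:
        return False
    a, b = t1.restrict(shared), t2.restrict(shared)
    taxa = frozenset(shared)
    bs = list(b.splits())
    return any(not splits_compatible(s, r, taxa) for s in a.splits() for r in bs)


def classify_evidence(call: BreakpointCall, s_hi: float = 0.95,
                      s_lo: float = 0.50) -> str:
    """Grade a breakpoint call: A when both flanking segments support
    topologically incompatible candidates at >= ``s_hi``; B when one flank is
    >= ``s_hi`` and the other >= ``s_lo``; C when both >= ``s_lo``.
    The call's class is the best grade over its breakpoints; it is stored on
    the call and returned."""
    best = "none"
    for i in range(len(call.positions)):
        ka, kb = call.segment_topologies[i], call.segment_topologies[i + 1]
        if not _trees_incompatible(call.candidates[ka], call.candidates[kb]):
            continue
        lo = min(call.segment_supports[i], call.segment_supports[i + 1])
        hi = max(call.segment_supports[i], call.segment_supports[i + 1])
        if lo >= s_hi:
            grade = "A"
        elif hi >= s_hi and lo >= s_lo:
            grade = "B"
        elif lo >= s_lo:
            grade = "C"
        else:
            continue
        if _CLASS_ORDER[grade] < _CLASS_ORDER[best]:
            best = grade
    call.evidence_class = best
    return best


def call_orb(screen: ScreenResult | None, call: BreakpointCall | None) -> bool:
    """ORB+ iff the phase-1 screen passed and phase 2 found a class A/B/C
    breakpoint.  Families that fail the screen never reach phase 2, so a
    missing ``call`` is ORB- by construction."""
    if screen is None or not screen.passed:
        return False
    return call is not None and call.evidence_class in ("A", "B", "C")


def nj_candidates(aln: Alignment, window: int = 200, step: int = 100,
                  min_sites: int = 50) -> list:
    """Neighbour-joining topologies from the full alignment and from sliding
    windows, used to propose segment genealogies beyond the reference and
    the family's own tree."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    codes = _encode(aln)
    names = list(aln.sequences)
    spans = [(0, aln.length)]
    if aln.length >= window + step:
        spans += [(s, min(s + window, aln.length))
                  for s in range(0, aln.length - min_sites, step)]
    out = []
    for s, e in spans:
        sub = codes[:, s:e]
        valid = (sub[:, None, :] != 255) & (sub[None, :, :] != 255)
        diff = (sub[:, None, :] != sub[None, :, :]) & valid
        nvalid = valid.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nvalid > 0, diff.sum(axis=2) / np.maximum(nvalid, 1), 0.0)
        p = np.minimum(p, 0.70)
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        try:
            tree = nj(DistanceMatrix(d, ids=names))
        except Exception:
            continue
        t = parse_newick(str(tree).strip())
        if t.n_leaves == len(names):
            out.append(t)
    return out
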