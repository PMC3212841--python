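"""Phase-1 recombination screen: three permutation statistics.

Recombination leaves a positional signal: sites that are physically close
tend to share a genealogy, so nearby informative sites are more mutually
compatible than distant ones.  Three site-order-sensitive statistics capture
this — a pairwise homoplasy index over nearby site pairs (PHI-style), a
neighbour similarity score over adjacent pairs (NSS), and a maximum
chi-squared contrast of per-pair mismatch densities either side of a sliding
split point (MaxChi).  Each is compared against a null obtained by permuting
the order of informative sites, which destroys positional signal while
preserving the site-frequency spectrum.

Sites are binarised (major state vs rest) so pairwise compatibility is the
classic four-gamete test, computed for all site pairs at once with bitmask
arithmetic.  A gene set passes the screen — and is forwarded to the
computationally heavier breakpoint-segmentation phase — when at least two of
the three one-sided permutation p-values fall below the significance level
(0.1 by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment

_STAT_NAMES = ("phi", "nss", "maxchi")


@dataclass
class ScreenResult:
    """Three permutation p-values and the 2-of-3 pass verdict."""

    p_values: dict
    statistics: dict = field(default_factory=dict)
    n_informative: int = 0
    alpha: float = 0.1

    @property
    def passed(self) -> bool:
        return sum(p < self.alpha for p in self.p_values.values()) >= 2


def _encode(aln: Alignment) -> np.ndarray:
    """(n, L) uint8 codes: ACGT -> 0..3, anything else (gap/ambiguity) -> 255."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    lut[ord("a")], lut[ord("c")], lut[ord("g")], lut[ord("t")] = 0, 1, 2, 3
    rows = [np.frombuffer(s.encode(), dtype=np.uint8) for s in
            aln.sequences.values()]
    return lut[np.vstack(rows)]


def _informative_binary(codes: np.ndarray):
    """Select parsimony-informative columns and binarise to major/minor.

    Returns (positions, binary matrix (n, s) in {0,1}, with missing values
    imputed to the major state).
    """
    n, L = codes.shape
    pos, cols = [], []
    for j in range(L):
        col = codes[:, j]
        ok = col != 255
        vals, counts = np.unique(col[ok], return_counts=True)
        if len(vals) < 2 or np.sort(counts)[-2] < 2:
            continue  # not parsimony-informative
        major = vals[np.argmax(counts)]
        b = (col != major).astype(np.uint8)
        b[~ok] = 0  # impute missing as major
        pos.append(j)
        cols.append(b)
    if not pos:
        return np.array([], dtype=int), np.zeros((n, 0), dtype=np.uint8)
    return np.asarray(pos), np.column_stack(cols)


def _incompatibility_matrix(binmat: np.ndarray) -> np.ndarray:
    """(s, s) bool: four-gamete incompatibility between binarised sites."""
    n, s = binmat.shape
    weights = (1 << np.arange(n, dtype=np.uint64))
    ones = (binmat.astype(np.uint64).T @ weights)          # bitmask of state 1
    zeros = ((1 - binmat).astype(np.uint64).T @ weights)   # bitmask of state 0
    a, b = ones[:, None], ones[None, :]
    c, d = zeros[:, None], zeros[None, :]
    return ((a & b) != 0) & ((a & d) != 0) & ((c & b) != 0) & ((c & d) != 0)


def _max_chi2(D: np.ndarray) -> float:
    """Max over sequence pairs and split points of the 2x2 chi-squared
    contrasting mismatch counts left/right of the split."""
    npairs, s = D.shape
    if s < 2:
        return 0.0
    cum = np.cumsum(D, axis=1, dtype=np.float64)
    total = cum[:, -1:]
    k = np.arange(1, s, dtype=np.float64)
    a = cum[:, :-1]                 # left mismatches
    b = k[None, :] - a              # left matches
    c = total - a                   # right mismatches
    d = (s - k)[None, :] - c        # right matches
    num = s * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(den > 0, num / den, 0.0)
    return float(chi.max())


def incompatibility_screen(aln: Alignment, n_permutations: int = 1000,
                           seed: int | None = None, alpha: float = 0.1,
                           window: int = 100,
                           max_pairs: int = 300) -> ScreenResult:
    """Run the three-statistic permutation screen on a nucleotide alignment.

    ``window`` is the maximum column separation (original alignment
    coordinates) for the PHI pair set; ``max_pairs`` caps the number of
    sequence pairs scanned by MaxChi (deterministically subsampled) to bound
    cost on large families.  P-values are one-sided in the direction
    recombination pushes each statistic, with the +1 correction, so they are
    never zero.  Fewer than two informative sites is an automatic fail with
    all p-values recorded as 1.
    """
    if aln.n_sequences < 4:
        raise ValueError(f"need >= 4 sequences, got {aln.n_sequences}")
    rng = np.random.default_rng(seed)
    codes = _encode(aln)
    pos, binmat = _informative_binary(codes)
    s = len(pos)
    fail = ScreenResult({k: 1.0 for k in _STAT_NAMES}, {}, s, alpha)
    if s < 2:
        return fail

    colpos = aln.column_map[pos]
    B = _incompatibility_matrix(binmat)

    # pair sets over informative-site indices
    ii, jj = np.triu_indices(s, k=1)
    near = (colpos[jj] - colpos[ii]) <= window
    phi_i, phi_j = ii[near], jj[near]
    adj_i, adj_j = np.arange(s - 1), np.arange(1, s)

    # sequence-pair mismatch matrix for MaxChi
    n = binmat.shape[0]
    pi, pj = np.triu_indices(n, k=1)
    if len(pi) > max_pairs:
        sel = np.linspace(0, len(pi) - 1, max_pairs).astype(int)
        pi, pj = pi[sel], pj[sel]
    D = (binmat[pi] != binmat[pj]).astype(np.float64)

    obs = {
        "phi": float(B[phi_i, phi_j].mean()) if len(phi_i) else None,
        "nss": float(1.0 - B[adj_i, adj_j].mean()),
        "maxchi": _max_chi2(D),
    }
    # mid-p tie handling: the null distributions are discrete (NSS
    # especially), and counting ties fully against the observed value makes
    # the test conservative; ties count half instead.
    beyond = {k: 0.0 for k in _STAT_NAMES}
    for _ in range(n_permutations):
        perm = rng.permutation(s)
        if obs["phi"] is not None:
            v = B[perm[phi_i], perm[phi_j]].mean()
            beyond["phi"] += 1.0 if v < obs["phi"] else \
                (0.5 if v == obs["phi"] else 0.0)
        v = 1.0 - B[perm[adj_i], perm[adj_j]].mean()
        beyond["nss"] += 1.0 if v > obs["nss"] else \
            (0.5 if v == obs["nss"] else 0.0)
        v = _max_chi2(D[:, perm])
        beyond["maxchi"] += 1.0 if v > obs["maxchi"] else \
            (0.5 if v == obs["maxchi"] else 0.0)
    p = {k: (1.0 if obs[k] is None
             else (1 + beyond[k]) / (n_permutations + 1))
         for k in _STAT_NAMES}
    return ScreenResult(p, {k: v for k, v in obs.items() if v is not None},
                        s, alpha)
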