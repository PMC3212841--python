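"""LGT classification, contingency tables and the association statistics.

A gene set's two evidence channels — tree discordance with the reference
and an observable recombination breakpoint (ORB) — combine into four
classes: ORB+ families are within-gene (fragmentary) lateral whether or not
their tree is discordant; discordant ORB- families are whole-gene lateral;
concordant ORB- families are vertical.  Families with a missing flag are
unclassified and never silently counted as vertical.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

WITHIN_GENE = "within_gene_lateral"
WHOLE_GENE = "whole_gene_lateral"
VERTICAL = "vertical"
UNCLASSIFIED = "unclassified"

#: exact rank-sum enumeration is used up to this pooled sample size
EXACT_RANKSUM_MAX_N = 16


def classify_gene_set(discordant, orb) -> str:
    """Map the (discordant, ORB) flag pair to an LGT class."""
    if discordant is None or orb is None:
        return UNCLASSIFIED
    if orb:
        return WITHIN_GENE
    return WHOLE_GENE if discordant else VERTICAL


@dataclass
class GeneSetRecord:
    """Per-family result row: flags, edit distance and regulator category."""

    family: str
    size: int
    discordant: bool | None = None
    orb: bool | None = None
    edit_distance: int | None = None
    edit_unresolved: bool = False
    regulator_category: str = "non-TF"
    lgt_class: str = field(default="")

    def __post_init__(self):
        if not self.lgt_class:
            self.lgt_class = classify_gene_set(self.discordant, self.orb)

    @property
    def lateral(self) -> bool | None:
        if self.lgt_class == UNCLASSIFIED:
            return None
        return self.lgt_class != VERTICAL


@dataclass
class ClassificationTable:
    """The discordant x ORB 2x2 bookkeeping with derived totals."""

    disc_orb: int = 0
    disc_noorb: int = 0
    conc_orb: int = 0
    conc_noorb: int = 0
    unclassified: int = 0

    @property
    def n_discordant(self) -> int:
        return self.disc_orb + self.disc_noorb

    @property
    def n_concordant(self) -> int:
        return self.conc_orb + self.conc_noorb

    @property
    def n_orb_positive(self) -> int:
        return self.disc_orb + self.conc_orb

    @property
    def n_classified(self) -> int:
        return self.n_discordant + self.n_concordant

    @property
    def lateral_count(self) -> int:
        return self.n_classified - self.conc_noorb

    @property
    def vertical_count(self) -> int:
        return self.conc_noorb

    @property
    def lateral_proportion(self) -> float:
        return self.lateral_count / self.n_classified if self.n_classified else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ORB+": [self.disc_orb, self.conc_orb, self.n_orb_positive],
             "ORB-": [self.disc_noorb, self.conc_noorb,
                      self.n_classified - self.n_orb_positive],
             "total": [self.n_discordant, self.n_concordant,
                       self.n_classified]},
            index=["discordant", "concordant", "total"])


def summarize(records, category_filter: str | None = None
              ) -> ClassificationTable:
    """Tally records (optionally one regulator category) into the 2x2 table."""
    table = ClassificationTable()
    selected = [r for r in records
                if category_filter is None
                or r.regulator_category == category_filter]
    if not selected:
        warnings.warn(f"no records selected (category={category_filter!r})")
        return table
    for r in selected:
        if r.discordant is None or r.orb is None:
            table.unclassified += 1
        elif r.discordant and r.orb:
            table.disc_orb += 1
        elif r.discordant:
            table.disc_noorb += 1
        elif r.orb:
            table.conc_orb += 1
        else:
            table.conc_noorb += 1
    return table


def fisher_association(group_a, group_b):
    """Fisher's exact test comparing two (successes, failures) groups.

    Returns (odds_ratio, two_sided_p, continuity_used); the odds ratio gets a
    0.5 continuity correction only when a cell is zero, and that is flagged.
    """
    a_s, a_f = group_a
    b_s, b_f = group_b
    cells = [a_s, a_f, b_s, b_f]
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if min(a_s + a_f, b_s + b_f, a_s + b_s, a_f + b_f) == 0:
        raise ValueError("zero margin in 2x2 table")
    _, p = stats.fisher_exact([[a_s, a_f], [b_s, b_f]], alternative="two-sided")
    continuity = 0 in cells
    if continuity:
        odds = ((a_s + 0.5) * (b_f + 0.5)) / ((a_f + 0.5) * (b_s + 0.5))
    else:
        odds = (a_s * b_f) / (a_f * b_s)
    return float(odds), float(p), continuity


def rank_sum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full enumeration over assignments, midranks for ties) when the
    pooled sample size is at most ``EXACT_RANKSUM_MAX_N``; otherwise the
    tie-corrected normal approximation of the Mann-Whitney test.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n1, n = a.size, a.size + b.size
    if n <= EXACT_RANKSUM_MAX_N:
        ranks = stats.rankdata(np.concatenate([a, b]))
        obs = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2.0
        dev = abs(obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        assert total == comb(n, n1)
        return hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def functional_enrichment(gene_categories: dict, subset,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-category over/under-representation of ``subset`` against the full
    gene complement, by Fisher's exact test with no multiple-testing
    correction; the frame notes the number of tests run instead."""
    subset = list(dict.fromkeys(subset))
    missing = [g for g in subset if g not in gene_categories]
    if missing:
        raise ValueError(f"subset genes without a category: {missing[:5]}")
    if not subset:
        warnings.warn("empty subset: no enrichment computed")
        return pd.DataFrame(columns=["category", "n_subset", "n_background",
                                     "p_value", "direction", "significant"])
    background = list(gene_categories)
    n_sub, n_bg = len(subset), len(background)
    sub_set = set(subset)
    rows = []
    cats = sorted(set(gene_categories.values()))
    for cat in cats:
        in_cat = {g for g, c in gene_categories.items() if c == cat}
        a = len(sub_set & in_cat)
        b = n_sub - a
        c = len(in_cat) - a
        d = (n_bg - n_sub) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "over" if a / n_sub > len(in_cat) / n_bg else "under"
        rows.append((cat, a, len(in_cat), float(p), direction, p < alpha))
    df = pd.DataFrame(rows, columns=["category", "n_subset", "n_background",
                                     "p_value", "direction", "significant"])
    df.attrs["n_tests"] = len(cats)
    return df


@dataclass
class CoTransferVerdict:
    """Whether a regulatory neighbourhood looks like one co-transferred unit."""

    neighbourhood_tf: str
    n_genes: int
    n_with_record: int
    all_orb_negative: bool | None
    all_discordant: bool | None
    same_history: bool | None  # None when taxon overlap < 4 or trees missing
    contains_breakpoint: bool | None

    @property
    def co_transfer_candidate(self) -> bool:
        return bool(self.all_orb_negative and self.all_discordant
                    and self.same_history)


def co_transfer_analysis(neighbourhood, records: dict, trees: dict,
                         collapse_threshold: float = 0.95) -> CoTransferVerdict:
    """Assess a regulatory neighbourhood for signatures of co-transfer.

    Clean co-transfer of a neighbourhood predicts: every member ORB-, every
    member discordant with the reference, and all member trees supporting an
    identical history (identical collapsed topologies on the shared taxa).
    A single ORB+ member instead marks within-region layering of transfers.
    """
    genes = list(neighbourhood.genes)
    if len(genes) < 2:
        raise ValueError("neighbourhood must contain >= 2 genes")
    recs = [records[g] for g in genes if g in records]
    flags_orb = [r.orb for r in recs if r.orb is not None]
    flags_disc = [r.discordant for r in recs if r.discordant is not None]
    all_orb_neg = (all(not f for f in flags_orb) if flags_orb else None)
    all_disc = (all(flags_disc) if flags_disc else None)
    has_bp = (any(flags_orb) if flags_orb else None)

    member_trees = [trees[g] for g in genes if g in trees]
    same: bool | None = None
    if len(member_trees) == len(genes) and member_trees:
        shared = frozenset.intersection(*(t.leaves for t in member_trees))
        if len(shared) >= 4:
            keys = {t.restrict(shared)
                     .collapse_low_support(collapse_threshold)
                     .topology_key()
                    for t in member_trees}
            same = len(keys) == 1
    return CoTransferVerdict(
        neighbourhood_tf=neighbourhood.tf,
        n_genes=len(genes),
        n_with_record=len(recs),
        all_orb_negative=all_orb_neg,
        all_discordant=all_disc,
        same_history=same,
        contains_breakpoint=has_bp,
    )
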