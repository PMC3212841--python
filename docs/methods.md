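# Methods

This note documents the models, algorithms and numerical choices behind
`lgtnet`, in the package's own terms: what each stage assumes, which knobs
matter, what the synthetic generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## Trees, splits and discordance

All comparisons are performed on **unrooted** trees.  A gene tree is
compared to the clade reference by (i) pruning the reference to the
family's taxon set, (ii) contracting every gene-tree edge with posterior
support below the collapse threshold (default 0.95, inclusive — an edge at
exactly the threshold is kept), and (iii) testing each remaining resolved
gene-tree split for pairwise compatibility against the pruned reference's
splits.  Polytomies produced by collapsing are treated as uncertainty, not
conflict: only a resolved split can make a family discordant.  Edges
without a support annotation are treated as fully supported.  Fewer than
four shared taxa is an error; such families are excluded upstream and
propagate as NA, never silently as "vertical".

## SPR edit distance

The distance is the minimum number of subtree-prune-and-regraft moves
between the support-collapsed gene tree and the pruned reference, each move
standing for one transfer event.  Exact computation is NP-hard, so the
implementation is exact-with-a-budget:

- **Common pendant subtree reduction** first: cherries present in both
  trees are iteratively merged into single leaves.  This is
  distance-preserving and typically shrinks a 27-taxon pair that differs by
  one or two transfers to well under ten effective leaves.
- **Bidirectional breadth-first search** over SPR neighbourhoods of the
  reduced pair, meeting in the middle, with canonical split-set hashing to
  deduplicate topologies.  The search is exact whenever it returns a
  number.
- **Budget**: depth d_max (default 6, mirroring the small fraction of
  families whose discordance is too complex to resolve) and a total
  expansion budget (default 3×10^5 generated trees).  Exceeding either
  returns UNRESOLVED — never an approximation.  On the default synthetic
  cohort ~4–5% of discordant families come back UNRESOLVED.

A collapsed (multifurcating) gene tree is first refined with every
reference split compatible with it, then any remaining polytomy is resolved
deterministically; uncertainty therefore never inflates the distance (a
tree whose resolved splits are all compatible with the reference refines to
the reference itself, distance 0).

Correctness is checked against an independent oracle: breadth-first search
over the complete SPR graph of tree space, exhaustively for all pairs of
5- and 6-leaf topologies and for a seeded sample of 7-leaf pairs (the full
7-leaf pair set — ~4.5×10^5 pairs — would dominate the suite's runtime
without changing what is being verified; the per-pair comparison is exact
either way).

## MRP reference tree

Every non-trivial gene-tree bipartition with PP ≥ 0.95 becomes one binary
character; each occurrence is its own character (a split seen in 50
families contributes 50 columns), and taxa absent from a family are missing
data for that family's columns.  The maximum-parsimony tree over this
matrix is searched by stepwise addition in a seeded random order (best
placement per leaf), followed by steepest-ascent NNI with a full SPR pass
whenever NNI stalls, over 10 random-addition restarts.  Fitch scoring packs
all characters into one big integer per node (two bits per character), so a
tree evaluation is O(taxa) integer operations; the search stops early when
a tree reaches the lower bound of one change per character (always the case
for conflict-free input).  Equally parsimonious results are tie-broken by
the lexicographically smallest newick string, making the output a pure
function of the seed.

## Two-phase recombination detection

**Phase 1 — screen.**  Informative sites (≥ 2 states each seen ≥ 2 times)
are binarised to major/minor state, and pairwise compatibility is the
four-gamete test computed for all site pairs at once with bitmask
arithmetic.  Three statistics are evaluated against a null that permutes
the order of informative sites (1000 permutations by default, seeded):

- *pairwise homoplasy index*: mean incompatibility over site pairs at most
  100 alignment columns apart (recombination lowers it);
- *neighbour similarity score*: compatible fraction of adjacent
  informative-site pairs (recombination raises it);
- *maximum chi-squared*: the largest 2×2 chi-squared contrasting per-pair
  mismatch counts left/right of a sliding split point.

P-values are one-sided in the direction recombination pushes each
statistic, with the +1 correction (never zero) and **mid-p tie handling**:
the NSS null in particular is strongly discrete, and counting ties fully
against the observed value deflated its type-I rate to ~0.06 at a nominal
0.1; counting ties half restores calibration (0.09–0.12 across statistics,
verified on 500 null alignments).  A family passes the screen when at
least two of the three p-values fall below 0.1, and only then proceeds to
phase 2 — families failing the screen are ORB− by construction.

**Phase 2 — segmentation.**  A deterministic penalized dynamic program
replaces a reversible-jump MCMC change-point sampler: candidate topologies
(the pruned reference, the family's own tree, and neighbour-joining trees
from the full alignment and 200-bp sliding windows, deduplicated) each get
a per-site log-likelihood profile under Jukes-Cantor with the trees' own
branch lengths (clamped to [1e-4, 5]; 0.05 where absent), and the program
maximizes total log-likelihood minus `penalty` per topology switch
(O(sites × candidates²)).  Relative, not absolute, fit is what matters
here, which is why a single-parameter substitution model suffices.

The **penalty default is 25 log-likelihood units**.  Rationale: candidate
topologies estimated from sliding windows overfit their own window by
roughly 10–20 log units on recombination-free data, while a genuine
topology change at study-scale divergence gains upwards of 30 over a
300-bp segment; 25 produced zero spurious class-A/B/C calls and ~0.93
breakpoint recovery on development simulations.  As the penalty → ∞ the
program always returns a single segment.

Breakpoints are 0-based, half-open: a reported position is the first
column of the right-hand segment, mapped back through the alignment's
column map when columns were trimmed.  Each breakpoint is graded by the
softmax likelihood weight of the chosen topology within each flanking
segment: class A when both flanks ≥ 0.95 and the flanking topologies are
mutually incompatible; B when one flank ≥ 0.95 and the other ≥ 0.50; C when
both ≥ 0.50.  The class thresholds are configuration (`s_hi`, `s_lo`): the
original A/B/C definitions live in external work, so the rule here is a
documented parameterized surrogate.  ORB+ requires a passed screen **and**
a class A/B/C breakpoint.

## Alignment handling

Block trimming follows the relaxed conserved-block recipe: a column is
conserved when its majority residue is shared by more than half the
sequences (count threshold floor(n·frac)+1, default frac 0.5 at both the
conserved and flank levels), runs of more than 50 contiguous non-conserved
columns are removed, surviving blocks are trimmed to flank-quality columns
and dropped below 5 columns, and gapped columns are allowed by default.
The retained-column index map is returned so downstream breakpoint
positions can always be reported in original coordinates.  Reverse
translation maps each aligned residue to its codon (gaps to `---`),
tolerates a terminal stop codon, and reports any CDS/protein mismatch with
the sequence name and residue position.

## Regulatory network

The TRN is a directed gene→gene graph read from RegulonDB-dialect TSVs
(regulator, target, effect, evidence; `#` comments skipped; both the
TF→gene and TF→TF files merged; duplicate edges collapsed; excluded
RNA/obsolete genes dropped and counted).  Heterodimeric TFs contribute one
node per subunit-encoding gene, each carrying the full target set.

- **Global regulators**: the k = 20 regulator *units* with most targets
  (heterodimer subunits with identical target sets count as one unit, so
  the gene set can exceed k — 20 units map to 22 genes when two are
  heterodimers).  Units tied with the k-th are all included, with a
  warning.
- **Neighbour regulators**: non-global TFs with a regulated target at
  chromosome rank ±1.  Adjacency is gene-order rank, circular (bacterial
  chromosome), ignoring strand and intergenic distance.  Self-regulation
  never counts as adjacency, and adjacent heterodimer subunits regulating
  only each other are excluded.
- **Regulatory neighbourhoods**: the maximal contiguous run of
  rank-adjacent regulated targets on either side of the TF, plus the TF
  itself.

Out-degree counts distinct targets; betweenness is directed shortest-path
betweenness (unnormalized ordered-pair counts, via networkx).

## Classification and statistics

The (discordant × ORB) pair maps to: ORB+ → within-gene (fragmentary)
lateral (including the "cryptic" concordant-but-ORB+ case); discordant and
ORB− → whole-gene lateral; concordant and ORB− → vertical; any NA flag →
unclassified (excluded from denominators).  Contingency tables carry their
own total-reconciliation invariants.

Fisher's exact test is two-sided (scipy's hypergeometric implementation,
cross-checked in the tests against full enumeration for every table with
row margins ≤ 12); the odds ratio gets a 0.5 continuity correction only
when a cell is zero, and that is flagged.  The rank-sum comparison is exact
(full enumeration over assignments with midranks) up to a pooled size of
16 and the tie-corrected normal approximation beyond.  No multiple-testing
correction is applied anywhere; reports instead state the number of tests
performed.  Functional enrichment compares a subset's per-category
frequency to the full gene complement by two-sided Fisher tests at α=0.05.

"Same evolutionary history" for the co-transfer analysis means identical
support-collapsed topologies on the intersection of the neighbourhood
members' taxon sets; an intersection below four taxa is reported NA.

## Synthetic-data generator

Defaults emulate the study's conditions at desk scale: 27 strains; 200
families of 4–27 taxa; 50.3% lateral of which 12.8 points are mosaic
(within-gene); transfers planted as 1–9 SPR moves with weights
(0.55, 0.20, 0.10, 0.05, 0.04, 0.02, 0.02, 0.01, 0.01), so ~75% of lateral
families need ≤ 2 moves; 200-codon alignments evolved under Jukes-Cantor
along the trees (species-tree edges ~ Exp(0.03) + 0.005 substitutions per
site); internal-edge supports drawn U(0.95, 1) so planted discordance
survives collapsing.  Mosaic families keep a reference-concordant tree for
their left segment and switch to an SPR-derived donor topology at a planted
codon-aligned breakpoint in the central 30–70% of the alignment (segments
under 30 columns are refused as undetectable by design).

The TRN generator plants 20 hub units (two heterodimeric → 22 genes) whose
degrees are drawn heavy-tailed above a hard floor of 40 targets and scaled
so hubs enact ~69% of all edges; 93 neighbour TFs sit adjacent to runs of
1–14 collinear targets (zipf-distributed run lengths, capped at the
study's observed maximum of 14); all other wiring keeps circular rank
distance ≥ 2 from the regulator, so planted distal-only TFs are never
accidental neighbours, while hubs may regulate adjacent genes (they are
excluded from the neighbour class by globality, as in the study).  Every
TF gene is mapped to a gene family so the network overlay has per-gene
transfer calls.

What the generator does **not** emulate: alignment error and tree-inference
error (gene trees are the true topologies with high supports — real
Bayesian trees add noise that discordance calls inherit), rate variation
across sites and lineages, indels/gaps, recombination tracts with external
donors, operon structure, and effect signs in the network.  Passing tests
therefore demonstrate the pipeline's correctness and calibration under the
stated generative model, not its robustness to inference error in real
data.

## Problem sizes in the test suite

The suite verifies: exact SPR distances against the BFS oracle (all 5- and
6-leaf pairs, 150 seeded 7-leaf pairs); MRP recovery for 100 random 8–27
leaf trees; screen type-I calibration on 500 null alignments (12 taxa,
600 bp, 200 permutations — the permutation count trades resolution for
runtime without affecting a 0.1 threshold); breakpoint localisation on 100
two-segment mosaics (donor two SPR moves away, breakpoint at column 300 of
600, ±50-column tolerance); and end-to-end label recovery on the default
200-family cohort (sensitivity ≥ 0.8, specificity ≥ 0.9, exact regulator
categories).  On the default cohort, whole-gene families are recovered
almost perfectly while mosaic-only recall is ~0.6 — small families (4–6
taxa) and single-move donors carry little detectable signal, which is a
property of the data, not a tunable of the detector.

## Known limitations

- The SPR search is exact only within its budget; deeply rearranged
  families (≥ 5 moves) may return UNRESOLVED.
- Donor/recipient direction along an SPR edit path is deliberately out of
  scope.
- The screen statistics operate on binarised sites; very high-divergence
  alignments with many multi-state columns lose some information.
- Evidence classes A/B/C are a parameterized surrogate for an external
  classification scheme, not a re-derivation of it.
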