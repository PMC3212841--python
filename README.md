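# lgtnet

Detecting **within-clade lateral genetic transfer (LGT)** — both of whole
genes and of within-gene fragments — among closely related bacterial
strains, and overlaying those calls on a **transcriptional regulatory
network (TRN)** to ask how transfer has shaped different modes of
regulation.

The package is aimed at microbial comparative genomicists: it takes
per-family gene trees (newick with posterior supports), nucleotide
alignments (FASTA) and a RegulonDB-style regulatory edge list, and produces
per-family transfer classifications, contingency tables and regulator-level
summaries.  A first-class synthetic-data generator emulates the whole study
at desk scale with ground-truth labels, so every stage is testable without
any downloads.

## The method

For a clade of *n* strains and a set of single-copy gene families
(*N* ≥ 4 taxa each):

1. **Reference tree (MRP).**  All gene-tree bipartitions with posterior
   probability PP ≥ 0.95 are recoded as binary characters (taxa absent from
   a family are missing data) and a maximum-parsimony supertree is searched
   by seeded hill-climbing (stepwise addition + NNI/SPR, with restarts).
2. **Whole-gene transfer = tree discordance.**  Each gene tree is collapsed
   at PP ≥ 0.95 and the reference is pruned to the family's taxa; a family
   is *discordant* when a resolved gene-tree split is incompatible with the
   pruned reference.  The minimum number of subtree-prune-and-regraft (SPR)
   moves reconciling the two trees — the *edit distance* d, each move one
   transfer event — is found exactly up to a budget d_max (default 6),
   otherwise reported UNRESOLVED.
3. **Within-gene transfer = observable recombination breakpoints (ORB).**
   A two-phase strategy: a fast screen of three site-order permutation
   statistics (pairwise homoplasy index, neighbour similarity score,
   maximum chi-squared; pass when ≥ 2 of 3 have p < 0.1), then a penalized
   dynamic-program segmentation that assigns candidate topologies to
   alignment segments by per-site Jukes-Cantor log-likelihood and reports
   breakpoints where the topology changes, graded into evidence classes
   A/B/C by flanking-segment support.
4. **Classification.**  ORB+ families are *within-gene (fragmentary)
   lateral* whether or not discordant; discordant ORB− families are
   *whole-gene lateral*; concordant ORB− families are *vertical*.
5. **TRN overlay.**  The directed TF→target network is built from
   RegulonDB-dialect edge lists; regulators are classed as *global* (top
   k = 20 by out-degree, heterodimer subunits counted as one unit),
   *neighbour* (non-global TFs regulating a chromosomally adjacent gene) or
   *other*, and transfer rates are compared across classes with Fisher's
   exact and Wilcoxon rank-sum tests.  Regulatory neighbourhoods (a
   neighbour TF plus its maximal run of collinear adjacent targets) are
   screened for co-transfer signatures.

## Worked example

Run the full synthetic study (200 families from a 27-strain clade, a
179-TF / 1533-target network) and print the summary:

```bash
lgtnet run -o runs/demo --seed 7
```

which ends with (abridged log):

```
INFO:lgtnet:simulated 200 families, TRN with 4046 edges
INFO:lgtnet:MRP matrix: 27 taxa x 2647 characters
INFO:lgtnet:discordant: 73 / 200 families
INFO:lgtnet:ORB+: 16 / 200 families
INFO:lgtnet:TF categories: 22 global / 93 neighbour / 64 other
INFO:lgtnet:lateral 89 / 200 (44.5%)
lateral: 89 / 200 families (44.5%)
```

Reading: 73 families have gene trees conflicting with the MRP reference
(whole-gene transfer signal), 16 carry an observable internal breakpoint
(within-gene transfer), and together 89 of 200 families (44.5%) show
evidence of transfer.  The 179 simulated TF genes resolve into 22 global
regulator genes (20 units, two of them heterodimers), 93 neighbour
regulators and 64 others — matching the planted categories exactly.
Against the generator's ground truth this run recovers lateral families
with sensitivity 0.87 and specificity 0.99.

Stages are individually runnable (`lgtnet simulate|mrp|discordance|
breakpoints|trn|classify|report`), share one output directory, and every
threshold and seed is recorded in `config.yaml` and `run.log`.

Library use mirrors the CLI:

```python
import lgtnet as L

ref = L.read_newick("runs/demo/mrp/reference.nwk")[0]
gene = L.read_newick("runs/demo/sim/trees/F0001.nwk")[0]
L.is_discordant(gene, ref, threshold=0.95)   # True/False
L.spr_edit_distance(gene, ref, d_max=6)      # EditResult(distance=1, ...)
```

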