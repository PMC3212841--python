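"""Pipeline orchestration: simulate -> MRP -> discordance -> breakpoints
-> TRN -> classification -> report.

Each stage reads only files written by earlier stages, so the stages are
individually runnable and composable from the command line.  Every
threshold and seed is recorded with the run for provenance.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from .alignment import read_fasta, write_fasta
from .breakpoints import (call_orb, classify_evidence, nj_candidates,
                          segment_alignment)
from .mrp import build_mrp_supertree, harvest_bipartitions
from .phylo import PhyloTree, is_discordant, read_newick, write_newick
from .screen import incompatibility_screen
from .simulate import Cohort, SimConfig, simulate_cohort
from .spr import spr_edit_distance
from .trn import (RegulatoryNetwork, build_trn, classify_global,
                  extract_neighbourhood, find_neighbour_regulators, read_loci)

log = logging.getLogger("lgtnet")


@dataclass
class PipelineConfig:
    """Every printed study constant is a named key with that default."""

    seed: int = 0
    pp_threshold: float = 0.95        # bipartition harvest support floor
    collapse_threshold: float = 0.95  # test-tree support collapse
    screen_alpha: float = 0.1         # phase-1 per-statistic significance
    n_permutations: int = 1000
    enrichment_alpha: float = 0.05
    k_global: int = 20
    d_max: int = 6
    s_hi: float = 0.95
    s_lo: float = 0.50
    segment_penalty: float = 25.0
    mrp_restarts: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_seed(seed: int, idx: int) -> int:
    return int((seed * 1_000_003 + idx) % (2 ** 31))


# -- stage: simulate ------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir) -> Cohort:
    out = Path(outdir) / "sim"
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.sim)
    write_newick(cohort.species_tree, out / "species_tree.nwk")
    fam_rows = []
    for f in cohort.families:
        write_newick(f.tree, out / "trees" / f"{f.family}.nwk")
        write_fasta(f.alignment, out / "alignments" / f"{f.family}.fasta")
        fam_rows.append((f.family, f.size, f.truth["lgt_class"],
                         f.truth["spr_moves"],
                         ",".join(map(str, f.truth["breakpoints"]))))
    pd.DataFrame(fam_rows, columns=["family", "size", "true_class",
                                    "true_spr_moves", "true_breakpoints"]
                 ).to_csv(out / "truth_families.tsv", sep="\t", index=False)

    tf_rows, tftf_rows = [], []
    for u, v in cohort.trn.graph.edges:
        row = (u, v, "+", "simulated")
        (tftf_rows if v in cohort.trn.tf_set else tf_rows).append(row)
    pd.DataFrame(tf_rows).to_csv(out / "network_tf_gene.tsv", sep="\t",
                                 index=False, header=False)
    pd.DataFrame(tftf_rows).to_csv(out / "network_tf_tf.tsv", sep="\t",
                                   index=False, header=False)
    loci_rows = [(l.gene, l.replicon, l.start, l.end, l.strand)
                 for l in sorted(cohort.loci.values(), key=lambda x: x.rank)]
    pd.DataFrame(loci_rows).to_csv(out / "loci.tsv", sep="\t", index=False,
                                   header=False)
    with open(out / "heterodimers.tsv", "w") as fh:
        for grp in cohort.trn.heterodimer_groups:
            fh.write("\t".join(sorted(grp)) + "\n")
    pd.DataFrame(sorted(cohort.gene_family_map.items()),
                 columns=["gene", "family"]).to_csv(
        out / "gene_families.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(cohort.gene_categories.items()),
                 columns=["gene", "category"]).to_csv(
        out / "gene_categories.tsv", sep="\t", index=False)
    tf_truth_rows = [(g, cat) for cat in ("global", "neighbour", "other")
                     for g in sorted(cohort.tf_truth[cat])]
    pd.DataFrame(tf_truth_rows, columns=["gene", "true_category"]).to_csv(
        out / "truth_tf.tsv", sep="\t", index=False)
    log.info("simulated %d families, TRN with %d edges",
             len(cohort.families), cohort.trn.n_edges)
    return cohort


def _family_ids(outdir) -> list:
    tdir = Path(outdir) / "sim" / "trees"
    return sorted(p.stem for p in tdir.glob("*.nwk"))


def _load_tree(outdir, fam) -> PhyloTree:
    return read_newick(Path(outdir) / "sim" / "trees" / f"{fam}.nwk")[0]


# -- stage: MRP reference ---------------------------------------------------------

def stage_mrp(config: PipelineConfig, outdir) -> PhyloTree:
    out = Path(outdir) / "mrp"
    out.mkdir(parents=True, exist_ok=True)
    trees = [_load_tree(outdir, f) for f in _family_ids(outdir)]
    matrix = harvest_bipartitions(trees, pp_threshold=config.pp_threshold)
    (out / "mrp_matrix.phy").write_text(matrix.to_phylip())
    ref = build_mrp_supertree(matrix, seed=_stage_seed(config.seed, 1),
                              n_restarts=config.mrp_restarts)
    write_newick(ref, out / "reference.nwk")
    log.info("MRP matrix: %d taxa x %d characters", len(matrix.taxa),
             matrix.n_columns)
    return ref


# -- stage: discordance ------------------------------------------------------------

def stage_discordance(config: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir) / "discordance"
    out.mkdir(parents=True, exist_ok=True)
    ref = read_newick(Path(outdir) / "mrp" / "reference.nwk")[0]
    rows = []
    for fam in _family_ids(outdir):
        tree = _load_tree(outdir, fam)
        disc = is_discordant(tree, ref, threshold=config.collapse_threshold)
        res = spr_edit_distance(tree, ref, d_max=config.d_max,
                                collapse_threshold=config.collapse_threshold)
        rows.append((fam, tree.n_leaves, disc,
                     "" if res.distance is None else res.distance,
                     res.unresolved))
    df = pd.DataFrame(rows, columns=["family", "size", "discordant",
                                     "edit_distance", "unresolved"])
    df.to_csv(out / "discordance.tsv", sep="\t", index=False)
    log.info("discordant: %d / %d families", int(df.discordant.sum()), len(df))
    return df


# -- stage: breakpoints --------------------------------------------------------------

def stage_breakpoints(config: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir) / "breakpoints"
    out.mkdir(parents=True, exist_ok=True)
    ref = read_newick(Path(outdir) / "mrp" / "reference.nwk")[0]
    rows = []
    for i, fam in enumerate(_family_ids(outdir)):
        aln = read_fasta(Path(outdir) / "sim" / "alignments" / f"{fam}.fasta")
        screen = incompatibility_screen(
            aln, n_permutations=config.n_permutations,
            seed=_stage_seed(config.seed, 100 + i),
            alpha=config.screen_alpha)
        positions, evidence, orb = [], "none", False
        if screen.passed:
            tree = _load_tree(outdir, fam)
            cands = [ref.restrict(aln.names), tree]
            cands += nj_candidates(aln)
            call = segment_alignment(aln, cands,
                                     penalty=config.segment_penalty)
            evidence = classify_evidence(call, s_hi=config.s_hi,
                                         s_lo=config.s_lo)
            positions = call.original_positions(aln.column_map)
            orb = call_orb(screen, call)
        rows.append((fam, screen.n_informative,
                     screen.p_values["phi"], screen.p_values["nss"],
                     screen.p_values["maxchi"], screen.passed,
                     ",".join(map(str, positions)), evidence, orb))
    df = pd.DataFrame(rows, columns=["family", "n_informative", "p_phi",
                                     "p_nss", "p_maxchi", "screen_passed",
                                     "positions", "evidence_class", "orb"])
    df.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
    log.info("ORB+: %d / %d families", int(df.orb.sum()), len(df))
    return df


# -- stage: TRN --------------------------------------------------------------------

def _load_trn(outdir) -> tuple:
    sim = Path(outdir) / "sim"
    het = []
    hpath = sim / "heterodimers.tsv"
    if hpath.exists():
        for line in hpath.read_text().splitlines():
            if line.strip():
                het.append(frozenset(line.split("\t")))
    net = build_trn(sim / "network_tf_gene.tsv", sim / "network_tf_tf.tsv")
    net.heterodimer_groups = het
    loci = read_loci(sim / "loci.tsv")
    return net, loci


def stage_trn(config: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir) / "trn"
    out.mkdir(parents=True, exist_ok=True)
    net, loci = _load_trn(outdir)
    global_set = classify_global(net, k=config.k_global)
    neighbours = find_neighbour_regulators(net, loci, global_set)
    rows = []
    for tf in sorted(net.tf_set):
        cat = ("global" if tf in global_set
               else "neighbour" if tf in neighbours else "other")
        rows.append((tf, cat, net.out_degree(tf), net.betweenness(tf)))
    df = pd.DataFrame(rows, columns=["gene", "category", "out_degree",
                                     "betweenness"])
    df.to_csv(out / "tf_categories.tsv", sep="\t", index=False)
    nb_rows = []
    for tf in sorted(neighbours):
        hood = extract_neighbourhood(net, loci, tf)
        nb_rows.append((tf, len(hood.targets), ",".join(hood.genes)))
    pd.DataFrame(nb_rows, columns=["tf", "n_targets", "genes"]).to_csv(
        out / "neighbourhoods.tsv", sep="\t", index=False)
    log.info("TF categories: %d global / %d neighbour / %d other",
             len(global_set), len(neighbours),
             len(net.tf_set) - len(global_set) - len(neighbours))
    return df


# -- stage: classification -------------------------------------------------------------

def stage_classify(config: PipelineConfig, outdir) -> dict:
    out = Path(outdir) / "classify"
    out.mkdir(parents=True, exist_ok=True)
    disc = pd.read_csv(Path(outdir) / "discordance" / "discordance.tsv",
                       sep="\t")
    bp = pd.read_csv(Path(outdir) / "breakpoints" / "breakpoints.tsv",
                     sep="\t")
    tfcat = pd.read_csv(Path(outdir) / "trn" / "tf_categories.tsv", sep="\t")
    gf = pd.read_csv(Path(outdir) / "sim" / "gene_families.tsv", sep="\t")
    fam_cat = {}
    cat_of_gene = dict(zip(tfcat.gene, tfcat.category))
    for gene, fam in zip(gf.gene, gf.family):
        if gene in cat_of_gene:
            fam_cat[fam] = cat_of_gene[gene]

    merged = disc.merge(bp[["family", "orb"]], on="family")
    records = []
    for row in merged.itertuples(index=False):
        ed = None if row.edit_distance == "" or pd.isna(row.edit_distance) \
            else int(row.edit_distance)
        records.append(cls.GeneSetRecord(
            family=row.family, size=int(row.size),
            discordant=bool(row.discordant), orb=bool(row.orb),
            edit_distance=ed, edit_unresolved=bool(row.unresolved),
            regulator_category=fam_cat.get(row.family, "non-TF")))
    rec_df = pd.DataFrame(
        [(r.family, r.size, r.discordant, r.orb,
          "" if r.edit_distance is None else r.edit_distance,
          r.edit_unresolved, r.regulator_category, r.lgt_class)
         for r in records],
        columns=["family", "size", "discordant", "orb", "edit_distance",
                 "unresolved", "regulator_category", "lgt_class"])
    rec_df.to_csv(out / "records.tsv", sep="\t", index=False)

    tables = {"overall": cls.summarize(records)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cat in ("global", "neighbour", "other"):
            tables[cat] = cls.summarize(records, category_filter=cat)
    for name, tab in tables.items():
        tab.to_frame().to_csv(out / f"table_{name}.tsv", sep="\t")

    stats: dict = {"n_tests": 0}
    nb, ov = tables["neighbour"], tables["overall"]
    if nb.n_classified and ov.n_classified > nb.n_classified:
        rest_orb = ov.n_orb_positive - nb.n_orb_positive
        rest_n = ov.n_classified - nb.n_classified
        _, p_excl, _ = cls.fisher_association(
            (nb.n_orb_positive, nb.n_classified - nb.n_orb_positive),
            (rest_orb, rest_n - rest_orb))
        _, p_incl, _ = cls.fisher_association(
            (nb.n_orb_positive, nb.n_classified - nb.n_orb_positive),
            (ov.n_orb_positive, ov.n_classified - ov.n_orb_positive))
        stats["neighbour_orb_vs_rest_p"] = p_excl
        stats["neighbour_orb_vs_all_p"] = p_incl
        stats["n_tests"] += 2
    ed_pos = [r.edit_distance for r in records
              if r.orb and r.edit_distance not in (None, 0)]
    ed_neg = [r.edit_distance for r in records
              if not r.orb and r.edit_distance not in (None, 0)]
    if ed_pos and ed_neg:
        stats["edit_distance_orbpos_vs_orbneg_p"] = \
            cls.rank_sum_compare(ed_pos, ed_neg)
        stats["n_tests"] += 1

    # regulator-count comparison: in-degree of genes in lateral vs vertical
    # families
    net, loci = _load_trn(outdir)
    fam_lateral = {r.family: r.lateral for r in records}
    gene_fam = dict(zip(gf.gene, gf.family))
    in_lat, in_vert = [], []
    for gene in net.nodes:
        fam = gene_fam.get(gene)
        lat = fam_lateral.get(fam)
        indeg = net.graph.in_degree(gene)
        if lat is None or indeg == 0:
            continue
        (in_lat if lat else in_vert).append(indeg)
    if in_lat and in_vert:
        stats["regulator_count_lateral_vs_vertical_p"] = \
            cls.rank_sum_compare(in_lat, in_vert)
        stats["n_tests"] += 1

    # functional enrichment of neighbour-regulated genes
    cats = pd.read_csv(Path(outdir) / "sim" / "gene_categories.tsv", sep="\t")
    gene_categories = dict(zip(cats.gene, cats.category))
    nb_tfs = tfcat.gene[tfcat.category == "neighbour"]
    regulated = sorted({t for tf in nb_tfs if tf in net.nodes
                        for t in net.targets_of(tf)})
    if regulated:
        enr = cls.functional_enrichment(gene_categories, regulated,
                                        alpha=config.enrichment_alpha)
        enr.to_csv(out / "enrichment_neighbour_targets.tsv", sep="\t",
                   index=False)
        stats["n_tests"] += enr.attrs["n_tests"]

    # co-transfer verdicts over regulatory neighbourhoods
    hoods = pd.read_csv(Path(outdir) / "trn" / "neighbourhoods.tsv", sep="\t")
    rec_by_fam = {r.family: r for r in records}
    gene_records, gene_trees = {}, {}
    for gene, fam in gene_fam.items():
        if fam in rec_by_fam:
            gene_records[gene] = rec_by_fam[fam]
            gene_trees[gene] = _load_tree(outdir, fam)
    verdict_rows = []
    for row in hoods.itertuples(index=False):
        genes = row.genes.split(",")
        if len(genes) < 2:
            continue
        from .trn import RegulatoryNeighbourhood
        hood = RegulatoryNeighbourhood(tf=row.tf,
                                       targets=[g for g in genes
                                                if g != row.tf],
                                       genes=genes)
        v = cls.co_transfer_analysis(hood, gene_records, gene_trees,
                                     collapse_threshold=config.collapse_threshold)
        verdict_rows.append((v.neighbourhood_tf, v.n_genes, v.n_with_record,
                             v.all_orb_negative, v.all_discordant,
                             v.same_history, v.contains_breakpoint,
                             v.co_transfer_candidate))
    vdf = pd.DataFrame(verdict_rows, columns=[
        "tf", "n_genes", "n_with_record", "all_orb_negative",
        "all_discordant", "same_history", "contains_breakpoint",
        "co_transfer_candidate"])
    vdf.to_csv(out / "co_transfer.tsv", sep="\t", index=False)
    if len(vdf):
        stats["neighbourhoods_with_breakpoint"] = int(
            vdf.contains_breakpoint.fillna(False).sum())
        stats["co_transfer_candidates"] = int(vdf.co_transfer_candidate.sum())

    summary = {
        "config": config.to_dict(),
        "n_families": len(records),
        "lateral_count": tables["overall"].lateral_count,
        "vertical_count": tables["overall"].vertical_count,
        "lateral_proportion": round(tables["overall"].lateral_proportion, 4),
        "orb_positive": tables["overall"].n_orb_positive,
        "discordant": tables["overall"].n_discordant,
        "tables": {name: dataclasses.asdict(tab)
                   for name, tab in tables.items()},
        "stats": stats,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("lateral %d / %d (%.1f%%)", summary["lateral_count"],
             summary["n_families"], 100 * summary["lateral_proportion"])
    return summary


def stage_report(config: PipelineConfig, outdir) -> str:
    with open(Path(outdir) / "classify" / "summary.json") as fh:
        summary = json.load(fh)
    lines = ["LGT classification summary",
             "==========================",
             f"families analysed : {summary['n_families']}",
             f"lateral           : {summary['lateral_count']} "
             f"({100 * summary['lateral_proportion']:.1f}%)",
             f"vertical          : {summary['vertical_count']}",
             f"ORB+              : {summary['orb_positive']}",
             f"discordant        : {summary['discordant']}",
             ""]
    for name, tab in sorted(summary["tables"].items()):
        lines.append(f"[{name}] discordantxORB cells: "
                     f"{tab['disc_orb']} / {tab['disc_noorb']} / "
                     f"{tab['conc_orb']} / {tab['conc_noorb']}")
    lines.append("")
    for k, v in sorted(summary["stats"].items()):
        lines.append(f"{k}: {v}")
    text = "\n".join(lines) + "\n"
    (Path(outdir) / "report.txt").write_text(text)
    return text


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        config.dump(outdir / "config.yaml")
        log.info("run config: %s", json.dumps(config.to_dict(),
                                              sort_keys=True))
        stage_simulate(config, outdir)
        stage_mrp(config, outdir)
        stage_discordance(config, outdir)
        stage_breakpoints(config, outdir)
        stage_trn(config, outdir)
        summary = stage_classify(config, outdir)
        stage_report(config, outdir)
        return summary
    finally:
        log.removeHandler(fh)
        fh.close()
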