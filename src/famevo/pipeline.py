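"""End-to-end orchestration: catalog -> phylogeny -> duplication ->
expression -> selection, with input validation and a consolidated report.

Every stage reads and writes plain-text interchange formats (TSV, FASTA,
Newick, BED, VCF), so each stage is independently testable and a run can
be resumed from any stage's outputs.  All stage parameters default to the
study's published settings (E-value 1e-5, 5-anchor blocks, 3-fold
high-expression rule, 0.001 pseudocount, lambda 6.1e-9, 20-kb/10-kb
windows, 10% missingness, 5% MAF, 1000 bootstrap replicates, lowest-5%
sweep quantile); one global seed drives every stochastic step via fixed
per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tomllib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import catalog, duplication, expression, phylogeny, selection

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Input paths and stage parameters for a full run."""

    # inputs
    gff3: str = ""
    pep_fasta: str = ""
    cds_fasta: str = ""
    domain_hits: str = ""
    homolog_hits: str = ""
    gene_order: str = ""
    alignment: str = ""
    reference_classes: str = ""
    tissue_fpkm: str = ""
    timecourse_fpkm: str = ""
    vcf: str = ""
    populations: str = ""
    gene_bed: str = ""
    outdir: str = "famevo_out"
    seed: int = 0
    # parameters (defaults = the study's published settings)
    evalue_max: float = 1e-5
    bootstrap_reps: int = 1000
    min_anchors: int = 5
    max_rank_gap: int = 25
    lambda_rate: float = 6.1e-9
    high_fold: float = 3.0
    inactive_floor: float = 1.0
    up_thresh: float = 1.0
    down_thresh: float = -1.0
    min_peak_fpkm: float = 0.5
    divergence_r: float = 0.5
    window_size: int = 20_000
    window_step: int = 10_000
    max_missing: float = 0.10
    min_maf: float = 0.05
    sweep_quantile: float = 0.05

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str) -> None:
        """Record every parameter actually used (effective configuration)."""
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1,
                      sort_keys=True)


def _stage(name: str):
    def deco(func):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return func(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("catalog")
def run_catalog(cfg: RunConfig) -> catalog.FamilyCatalog:
    genes = catalog.load_annotation(cfg.gff3, cfg.pep_fasta, cfg.cds_fasta)
    hits = catalog.read_domain_hits(cfg.domain_hits)
    fam = catalog.select_family(genes, hits, evalue_max=cfg.evalue_max)
    fam.to_tsv(os.path.join(cfg.outdir, "catalog.tsv"))
    chrom_counts, scaffold_counts = catalog.chromosome_distribution(fam)
    pd.concat([chrom_counts, scaffold_counts]).rename("n_genes") \
        .to_csv(os.path.join(cfg.outdir, "chromosome_counts.tsv"), sep="\t")
    return fam


@_stage("phylogeny")
def run_phylogeny(cfg: RunConfig) -> dict[str, str]:
    aln = phylogeny.read_alignment(cfg.alignment)
    tree = phylogeny.bootstrap(aln, n_reps=cfg.bootstrap_reps,
                               seed=cfg.seed + 1)
    phylogeny.write_tree(tree, os.path.join(cfg.outdir, "family_tree.nwk"))
    refs = phylogeny.read_reference_labels(cfg.reference_classes)
    classes = phylogeny.assign_classes(tree, refs)
    phylogeny.write_class_map(classes,
                              os.path.join(cfg.outdir, "classes.tsv"))
    return classes


@_stage("duplication")
def run_duplication(cfg: RunConfig, fam: catalog.FamilyCatalog):
    hits = duplication.read_homolog_hits(cfg.homolog_hits)
    order = duplication.read_gene_order(cfg.gene_order)
    blocks = duplication.detect_blocks(
        hits, order, min_anchors=cfg.min_anchors,
        max_rank_gap=cfg.max_rank_gap, evalue_max=cfg.evalue_max)
    duplication.write_blocks(blocks, os.path.join(cfg.outdir, "blocks.tsv"))

    members = set(fam.member_ids)
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, (chrom, rank) in order.items():
        by_chrom.setdefault(chrom, []).append((rank, gene))
    catalog_order = {c: [g for _, g in sorted(v)]
                     for c, v in by_chrom.items()}
    tandem = duplication.classify_tandem(catalog_order, members)
    segmental, pairs = duplication.classify_segmental(blocks, members)

    from Bio import SeqIO
    cds = {rec.id: str(rec.seq).upper()
           for rec in SeqIO.parse(cfg.cds_fasta, "fasta")}
    pair_df = duplication.analyze_pairs(pairs, cds,
                                        lambda_rate=cfg.lambda_rate)
    pair_df.to_csv(os.path.join(cfg.outdir, "pairs.tsv"), sep="\t",
                   index=False, float_format="%.4f")
    summary = duplication.summarize_duplication(
        list(pair_df["wgd_bin"]), tandem, segmental, len(members))
    summary.to_csv(os.path.join(cfg.outdir, "duplication_summary.tsv"),
                   sep="\t", index=False)
    return blocks, tandem, segmental, pairs, pair_df, summary


@_stage("expression")
def run_expression(cfg: RunConfig, pairs: list[tuple[str, str]]):
    tissue = expression.read_fpkm(cfg.tissue_fpkm)
    labels = expression.classify_tissue_table(
        tissue, fold=cfg.high_fold, floor_fpkm=cfg.inactive_floor)
    labels.to_csv(os.path.join(cfg.outdir, "expression_labels.tsv"),
                  sep="\t", float_format="%.4f")
    timecourse = expression.read_fpkm(cfg.timecourse_fpkm)
    responses = expression.classify_responses(
        timecourse, up_thresh=cfg.up_thresh, down_thresh=cfg.down_thresh,
        min_peak_fpkm=cfg.min_peak_fpkm)
    responses.to_csv(os.path.join(cfg.outdir, "infection_response.tsv"),
                     sep="\t", float_format="%.4f")
    rows = []
    for a, b in pairs:
        if a in tissue.index and b in tissue.index:
            verdict = expression.pair_divergence(
                tissue.loc[a], tissue.loc[b], r_thresh=cfg.divergence_r)
            rows.append({"gene_a": a, "gene_b": b, "pattern": verdict})
    pair_div = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pattern"])
    pair_div.to_csv(os.path.join(cfg.outdir, "pair_divergence.tsv"),
                    sep="\t", index=False)
    return labels, responses, pair_div


@_stage("selection")
def run_selection(cfg: RunConfig):
    if not os.path.exists(cfg.vcf):
        raise FileNotFoundError(f"VCF not found: {cfg.vcf}")
    pops = selection.read_population_table(cfg.populations)
    table = selection.read_vcf(cfg.vcf, pops)
    table = selection.filter_variants(table, max_missing=cfg.max_missing,
                                      min_maf=cfg.min_maf)
    from cyvcf2 import VCF
    vcf = VCF(cfg.vcf)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    windows = {}
    for chrom in np.unique(table.chrom):
        ln = lengths.get(chrom) or int(table.pos[table.chrom == chrom].max())
        windows[chrom] = selection.make_windows(ln, cfg.window_size,
                                                cfg.window_step)
    pi_w = selection.window_pi(table, "wild", windows)
    pi_c = selection.window_pi(table, "cultivated", windows)
    scan = selection.ratio_scan(pi_w, pi_c)
    selection.write_scan(scan, os.path.join(cfg.outdir, "windows.tsv"))
    genes = selection.read_gene_bed(cfg.gene_bed)
    report, threshold = selection.call_sweeps(scan, genes,
                                              quantile=cfg.sweep_quantile)
    report.to_csv(os.path.join(cfg.outdir, "sweep_report.tsv"), sep="\t",
                  index=False, float_format="%.6g")
    regions = [(g.chromosome, g.start, g.end)
               for g in report[report.top5_selected].itertuples()]
    if regions:
        tree = selection.accession_tree(table, regions)
        phylogeny.write_tree(
            tree, os.path.join(cfg.outdir, "accession_tree.nwk"))
    return scan, report, threshold


def run_all(cfg: RunConfig) -> pd.DataFrame:
    """Execute every stage in dependency order and write the summary."""
    os.makedirs(cfg.outdir, exist_ok=True)
    cfg.dump(os.path.join(cfg.outdir, "effective_config.json"))

    fam = run_catalog(cfg)
    classes = run_phylogeny(cfg)
    blocks, tandem, segmental, pairs, pair_df, dup_summary = \
        run_duplication(cfg, fam)
    labels, responses, pair_div = run_expression(cfg, pairs)
    scan, sweep_report, threshold = run_selection(cfg)

    rows = [("family_size", len(fam.members))]
    class_counts = pd.Series(list(classes.values())).value_counts()
    for cls in sorted(class_counts.index):
        rows.append((f"class_{cls}", int(class_counts[cls])))
    rows += [("collinear_pairs", len(pairs)),
             ("synteny_blocks", len(blocks))]
    for _, rec in dup_summary.iterrows():
        rows.append((f"{rec['metric']}_count", int(rec['count'])))
        rows.append((f"{rec['metric']}_pct", float(rec['percent'])))
    for name, series in (("expression", labels["specificity"]),
                         ("activity", labels["activity"]),
                         ("level", labels["expression_level"]),
                         ("response", responses["category"])):
        for value, count in series.value_counts().items():
            rows.append((f"{name}_{value}", int(count)))
    distinct = int((pair_div["pattern"] == "distinct").sum())
    rows += [
        ("pairs_distinct", distinct),
        ("pairs_distinct_pct",
         round(100.0 * distinct / len(pair_div), 1) if len(pair_div)
         else 0.0),
        ("sweep_threshold", threshold),
        ("genes_below_chromosome_mean",
         int(sweep_report["below_chromosome_mean"].sum())),
        ("genes_above_chromosome_mean_pct",
         round(100.0 * (~sweep_report["below_chromosome_mean"]).sum()
               / len(sweep_report), 1)),
        ("sweep_selected_genes",
         int(sweep_report["top5_selected"].sum())),
    ]
    summary = pd.DataFrame(rows, columns=["metric", "value"])
    summary.to_csv(os.path.join(cfg.outdir, "summary.tsv"), sep="\t",
                   index=False)
    selected = sorted(sweep_report[sweep_report.top5_selected].gene_id)
    with open(os.path.join(cfg.outdir, "sweep_genes.txt"), "w") as fh:
        fh.write("\n".join(selected) + ("\n" if selected else ""))
    log.info("run complete: %d family members, %d collinear pairs, "
             "%d sweep genes", len(fam.members), len(pairs), len(selected))
    return summary


def make_synthetic_run(outdir: str, seed: int,
                       sim_config=None) -> RunConfig:
    """Generate a complete synthetic input bundle and its run config.

    Writes the genome bundle, the expression tables for the planted
    family, the two-population panel with the family genes placed on the
    panel chromosomes, and a ``run.toml``; returns the ready RunConfig.
    """
    from . import synthetic

    cfg = sim_config or synthetic.SimConfig()
    os.makedirs(outdir, exist_ok=True)
    bundle = synthetic.gen_genome(cfg, seed)
    paths = bundle.write(outdir)
    family = sorted(bundle.truth.family)

    tissue, timecourse, expr_truth = synthetic.gen_expression(
        cfg, seed + 1, family)
    tissue_path = os.path.join(outdir, "tissue_fpkm.tsv")
    tc_path = os.path.join(outdir, "timecourse_fpkm.tsv")
    tissue.to_csv(tissue_path, sep="\t")
    timecourse.to_csv(tc_path, sep="\t")
    expr_truth.to_json(os.path.join(outdir, "expression_truth.json"))

    table, genes, pop_truth = synthetic.gen_population(cfg, seed + 2, family)
    vcf_path = os.path.join(outdir, "panel.vcf")
    pops_path = os.path.join(outdir, "populations.tsv")
    bed_path = os.path.join(outdir, "genes.bed")
    synthetic.write_vcf(table, vcf_path, synthetic.chrom_lengths(cfg))
    synthetic.write_population_table(table.populations, pops_path)
    synthetic.write_gene_bed(genes, bed_path)
    pop_truth.to_json(os.path.join(outdir, "population_truth.json"))

    run_cfg = RunConfig(
        gff3=paths["gff3"], pep_fasta=paths["pep"], cds_fasta=paths["cds"],
        domain_hits=paths["domhits"], homolog_hits=paths["homologs"],
        gene_order=paths["order"], alignment=paths["aln"],
        reference_classes=paths["refs"], tissue_fpkm=tissue_path,
        timecourse_fpkm=tc_path, vcf=vcf_path, populations=pops_path,
        gene_bed=bed_path, outdir=os.path.join(outdir, "results"),
        seed=seed)
    toml_path = os.path.join(outdir, "run.toml")
    with open(toml_path, "w") as fh:
        for key, value in dataclasses.asdict(run_cfg).items():
            if isinstance(value, str):
                fh.write(f'{key} = "{value}"\n')
            else:
                fh.write(f"{key} = {value}\n")
    return run_cfg


def validate_inputs(cfg: RunConfig) -> list[dict]:
    """Per-file format and cross-file id checks; reports, never raises."""
    checks: list[dict] = []

    def record(name: str, ok: bool, message: str = "") -> None:
        checks.append({"check": name, "ok": ok, "message": message})

    genes = None
    try:
        genes = catalog.load_annotation(cfg.gff3, cfg.pep_fasta,
                                        cfg.cds_fasta)
        record("gff3", True, f"{len(genes)} gene models")
    except Exception as exc:
        record("gff3", False, str(exc))

    known_ids: set[str] = {g.gene_id for g in genes} if genes else set()
    for name, path in (("domain_hits", cfg.domain_hits),
                       ("homolog_hits", cfg.homolog_hits)):
        try:
            if name == "domain_hits":
                df = catalog.read_domain_hits(path)
                ids = set(df["gene_id"])
            else:
                df = duplication.read_homolog_hits(path)
                ids = set(df["query"]) | set(df["subject"])
            unknown = ids - known_ids if known_ids else set()
            record(name, not unknown,
                   f"{len(unknown)} unknown gene ids" if unknown
                   else f"{len(df)} rows")
        except Exception as exc:
            record(name, False, str(exc))

    for name, path in (("tissue_fpkm", cfg.tissue_fpkm),
                       ("timecourse_fpkm", cfg.timecourse_fpkm)):
        try:
            df = expression.read_fpkm(path)
            unknown = set(df.index) - known_ids if known_ids else set()
            record(name, not unknown,
                   f"{len(unknown)} genes absent from the catalog"
                   if unknown else f"{df.shape[0]}x{df.shape[1]}")
        except Exception as exc:
            record(name, False, str(exc))

    try:
        pops = selection.read_population_table(cfg.populations)
        table = selection.read_vcf(cfg.vcf, pops)
        record("vcf", True, f"{table.n_sites} sites, "
               f"{len(table.samples)} accessions")
    except Exception as exc:
        record("vcf", False, str(exc))

    try:
        bed = selection.read_gene_bed(cfg.gene_bed)
        record("gene_bed", True, f"{len(bed)} genes")
    except Exception as exc:
        record("gene_bed", False, str(exc))
    return checks
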