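"""Synthetic input generator with planted ground truth.

Emulates the full input bundle of a genome-wide gene-family study at desk
scale: a gene catalog with planted tandem arrays and duplicated segments,
coding sequences evolved at chosen synonymous divergence (Ks) and
selection intensity (omega), tissue and infection-time-course FPKM tables
with planted expression classes, and a two-population genotype panel with
planted low-diversity sweep regions.  Every generator is a pure function
of (config, seed), so reruns are byte-identical, and the planted labels
are returned as ground truth for recovery experiments.

Design notes: codon evolution applies per-site nucleotide proposals and
thins nonsynonymous ones with acceptance probability omega (stop codons
are never introduced), which matches the uniform-mutation assumptions of
the NG86 estimator it is used to validate.  The population generator
works at the allele-frequency level (no coalescent): wild frequencies are
drawn from a U-shaped Beta, cultivated frequencies follow by a
Beta-binomial-style drift kernel (the domestication bottleneck), and
inside planted sweep regions an extra push to fixation reduces expected
cultivated heterozygosity by the configured factor.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .duplication import _STOPS, _aa, _syn_sites
from .selection import VariantTable

log = logging.getLogger(__name__)

_SENSE_CODONS = tuple(sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS))
_CLASS_LABELS = ("I", "II", "III", "IV", "V", "VI")
_NUCS = "ACGT"


@dataclass
class SimConfig:
    """Study-scale defaults for every synthetic input.

    The desk-scale genome holds 1000 genes on 4 chromosomes with a
    93-member family (the size of the soybean laccase family); the
    population panel holds 62 wild and 240 cultivated accessions (the
    published resequencing panel split) on 4 chromosomes of 2 Mb with
    three planted 100-kb sweep regions at a 10-fold diversity reduction.
    """

    # genome
    n_chromosomes: int = 4
    genes_per_chromosome: int = 250
    family_fraction: float = 0.093
    tandem_cluster_sizes: tuple[int, ...] = (3, 2, 2, 3, 2)
    n_segmental_blocks: int = 4
    block_anchors: int = 8
    family_anchor_offsets: tuple[int, ...] = (0, 3, 6)
    cds_codons: int = 300
    pair_ks_levels: tuple[float, ...] = (0.15, 0.8, 1.8)
    within_class_ks: float = 0.1
    omega: float = 0.2
    n_classes: int = 5
    # expression
    tissues: tuple[str, ...] = ("root", "root_hair", "nodules", "pod",
                                "seed", "stem", "sam", "leaves", "flower")
    timepoints: tuple[str, ...] = ("0h", "0.5h", "3h", "6h", "12h")
    n_constitutive: int = 11
    n_specific: int = 8
    n_inactive: int = 11
    n_induced: int = 9
    n_suppressed: int = 12
    expr_noise_sigma: float = 0.2
    # population
    pop_n_chromosomes: int = 4
    pop_chrom_length: int = 2_000_000
    snp_density: float = 0.004
    n_wild: int = 62
    n_cultivated: int = 240
    wild_beta_shape: float = 0.3
    bottleneck_k: float = 30.0
    n_sweep_regions: int = 3
    sweep_span: int = 100_000
    sweep_reduction: float = 10.0
    missing_rate: float = 0.02
    high_missing_fraction: float = 0.02
    high_missing_rate: float = 0.3
    gene_span: int = 3_000

    @property
    def family_size(self) -> int:
        total = self.n_chromosomes * self.genes_per_chromosome
        return int(round(self.family_fraction * total))

    def validate(self) -> None:
        numeric = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)
                   if isinstance(getattr(self, f.name), (int, float))}
        bad = [k for k, v in numeric.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive config values: {bad}")
        if self.sweep_reduction <= 1:
            raise ValueError("sweep reduction factor must exceed 1")
        if max(self.tandem_cluster_sizes) >= self.genes_per_chromosome:
            raise ValueError("tandem cluster larger than a chromosome")
        if self.n_classes > len(_CLASS_LABELS):
            raise ValueError("too many classes")

    @classmethod
    def from_file(cls, path: str) -> "SimConfig":
        """Read a flat `key = value` text file (tuples comma-separated)."""
        values: dict = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as handle:
            for line in handle:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"{path}: unknown config key {key!r}")
                default = getattr(cls, key, None)
                if isinstance(default, tuple):
                    parts = [p.strip() for p in raw.split(",") if p.strip()]
                    elem = type(default[0])
                    values[key] = tuple(elem(p) for p in parts)
                elif isinstance(default, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(raw)
                elif isinstance(default, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        cfg = cls(**values)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted labels, mutually consistent with the emitted files."""

    family: list[str] = field(default_factory=list)
    classes: dict[str, str] = field(default_factory=dict)
    tandem: list[str] = field(default_factory=list)
    segmental: list[str] = field(default_factory=list)
    collinear_pairs: list[tuple[str, str, float, str]] = \
        field(default_factory=list)  # (a, b, ks_target, wgd_bin)
    tissue_labels: dict[str, str] = field(default_factory=dict)
    response_labels: dict[str, str] = field(default_factory=dict)
    sweep_regions: list[tuple[str, int, int]] = field(default_factory=list)
    sweep_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as handle:
            raw = json.load(handle)
        raw["collinear_pairs"] = [tuple(p) for p in raw["collinear_pairs"]]
        raw["sweep_regions"] = [tuple(r) for r in raw["sweep_regions"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int,
                start_atg: bool = True) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    codons = [_SENSE_CODONS[i] for i in body]
    first = "ATG" if start_atg else "CTG"
    return first + "".join(codons) + "TAA"


def _evolve_lineage(seq: str, n_syn_events: int, omega: float,
                    rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply substitutions until ``n_syn_events`` synonymous ones accepted.

    Proposals pick a uniform body position and a uniform alternative
    nucleotide; synonymous proposals are always accepted, nonsynonymous
    ones with probability omega, stop-introducing ones never.  The first
    and last codons are immutable (preserves the ORF).
    """
    chars = list(seq)
    n = len(chars)
    syn = nonsyn = 0
    while syn < n_syn_events:
        pos = int(rng.integers(3, n - 3))
        old = chars[pos]
        new = _NUCS[int(rng.integers(4))]
        if new == old:
            continue
        cstart = pos - pos % 3
        codon_old = "".join(chars[cstart:cstart + 3])
        codon_new = (codon_old[:pos - cstart] + new
                     + codon_old[pos - cstart + 1:])
        if codon_new in _STOPS:
            continue
        if _aa(codon_new) == _aa(codon_old):
            chars[pos] = new
            syn += 1
        elif rng.random() < omega:
            chars[pos] = new
            nonsyn += 1
    return "".join(chars), syn, nonsyn


def _syn_site_total(seq: str) -> float:
    return sum(_syn_sites(seq[i:i + 3]) for i in range(0, len(seq), 3)
               if seq[i:i + 3] not in _STOPS)


def evolve_cds_pair(
    length: int,
    ks_target: float,
    omega: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ancestor: str | None = None,
) -> tuple[str, str, dict]:
    """Evolve two coding sequences from a common ancestor.

    ``length`` is in codons (including the fixed ATG and stop); the total
    number of synonymous substitutions across both lineages is Poisson
    with mean ``ks_target`` x (synonymous sites of the ancestor), so the
    expected NG86 Ks of the pair is ``ks_target``.  Nonsynonymous changes
    are thinned by omega.  Returns (cds_a, cds_b, realized-event counts).
    """
    if length < 50:
        raise ValueError("need at least 50 codons")
    if ks_target < 0:
        raise ValueError("negative Ks target")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = _random_cds(rng, length)
    s_sites = _syn_site_total(ancestor)
    if ks_target > 2.0:
        log.warning("Ks target %.2f approaches saturation of the "
                    "Jukes-Cantor correction", ks_target)
    total = int(rng.poisson(ks_target * s_sites))
    split = int(rng.binomial(total, 0.5))
    a, syn_a, non_a = _evolve_lineage(ancestor, split, omega, rng)
    b, syn_b, non_b = _evolve_lineage(ancestor, total - split, omega, rng)
    realized = {"syn_events": syn_a + syn_b,
                "nonsyn_events": non_a + non_b,
                "syn_sites_ancestor": s_sites}
    return a, b, realized


# ---------------------------------------------------------------------------
# Genome bundle
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    locus: str
    transcript: str
    chrom: str
    rank: int
    strand: str
    cds: str
    n_exons: int
    is_family: bool = False
    class_label: str | None = None


@dataclass
class GenomeBundle:
    config: SimConfig
    genes: list[_Gene]
    extra_transcripts: list[_Gene]   # secondary mRNAs of multi-mRNA loci
    domain_hits: pd.DataFrame
    homolog_hits: pd.DataFrame
    truth: GroundTruth
    reference_peptides: dict[str, str]   # class-anchor taxa for the tree
    reference_labels: dict[str, str]

    def gene_order(self) -> dict[str, tuple[str, int]]:
        return {g.transcript: (g.chrom, g.rank) for g in self.genes}

    def catalog_order(self) -> dict[str, list[str]]:
        order: dict[str, list[str]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.rank)):
            order.setdefault(g.chrom, []).append(g.transcript)
        return order

    def write(self, outdir) -> dict[str, str]:
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {key: os.path.join(outdir, name) for key, name in [
            ("gff3", "genes.gff3"), ("pep", "pep.fasta"),
            ("cds", "cds.fasta"), ("domhits", "domain_hits.tsv"),
            ("homologs", "homolog_hits.tsv"), ("order", "gene_order.tsv"),
            ("aln", "family_aln.fasta"), ("refs", "reference_classes.tsv"),
            ("truth", "genome_truth.json")]}
        self._write_gff3(paths["gff3"])
        self._write_fastas(paths["pep"], paths["cds"])
        self.domain_hits.to_csv(paths["domhits"], sep="\t", index=False)
        self.homolog_hits.to_csv(paths["homologs"], sep="\t", index=False)
        order = pd.DataFrame(
            [(g.transcript, g.chrom, g.rank) for g in self.genes],
            columns=["gene_id", "chromosome", "rank"])
        order.to_csv(paths["order"], sep="\t", index=False)
        self._write_alignment(paths["aln"])
        with open(paths["refs"], "w") as handle:
            handle.write("taxon\tclass\n")
            for taxon in sorted(self.reference_labels):
                handle.write(f"{taxon}\t{self.reference_labels[taxon]}\n")
        self.truth.to_json(paths["truth"])
        return paths

    def _transcript_layout(self, gene: _Gene):
        """Exon/CDS genomic intervals (0-based half-open) for one mRNA."""
        utr5, utr3 = 100, 150
        tx_len = utr5 + len(gene.cds) + utr3
        n_ex = gene.n_exons
        exon_len = tx_len // n_ex
        lengths = [exon_len] * (n_ex - 1) + [tx_len - exon_len * (n_ex - 1)]
        start = gene.rank * 5000
        exons, offset, genome = [], 0, start
        for ln in lengths:
            exons.append((genome, genome + ln, offset, offset + ln))
            offset += ln
            genome += ln + 100  # fixed 100-bp introns
        cds_lo, cds_hi = utr5, utr5 + len(gene.cds)
        cds_spans = []
        for gs, ge, ts, te in exons:
            lo, hi = max(ts, cds_lo), min(te, cds_hi)
            if lo < hi:
                cds_spans.append((gs + (lo - ts), gs + (hi - ts)))
        span = (start, exons[-1][1])
        return span, [(gs, ge) for gs, ge, *_ in exons], cds_spans

    def _write_gff3(self, path: str) -> None:
        by_locus: dict[str, list[_Gene]] = {}
        for g in self.genes + self.extra_transcripts:
            by_locus.setdefault(g.locus, []).append(g)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.rank)):
                models = sorted(by_locus[g.locus],
                                key=lambda m: m.transcript)
                spans = [self._transcript_layout(m)[0] for m in models]
                lo = min(s for s, _ in spans)
                hi = max(e for _, e in spans)
                fh.write(f"{g.chrom}\tfamevo_sim\tgene\t{lo + 1}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={g.locus}\n")
                for m in models:
                    (ms, me), exons, cds = self._transcript_layout(m)
                    fh.write(f"{m.chrom}\tfamevo_sim\tmRNA\t{ms + 1}\t{me}"
                             f"\t.\t{m.strand}\t.\tID={m.transcript};"
                             f"Parent={m.locus}\n")
                    for es, ee in exons:
                        fh.write(f"{m.chrom}\tfamevo_sim\texon\t{es + 1}\t"
                                 f"{ee}\t.\t{m.strand}\t.\t"
                                 f"Parent={m.transcript}\n")
                    for cs, ce in cds:
                        fh.write(f"{m.chrom}\tfamevo_sim\tCDS\t{cs + 1}\t"
                                 f"{ce}\t.\t{m.strand}\t0\t"
                                 f"Parent={m.transcript}\n")

    def _write_fastas(self, pep_path: str, cds_path: str) -> None:
        with open(pep_path, "w") as pep, open(cds_path, "w") as cds:
            for g in sorted(self.genes + self.extra_transcripts,
                            key=lambda g: g.transcript):
                peptide = str(Seq(g.cds).translate()).rstrip("*")
                pep.write(f">{g.transcript}\n{peptide}\n")
                cds.write(f">{g.transcript}\n{g.cds}\n")

    def _write_alignment(self, path: str) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes, key=lambda g: g.transcript):
                if g.is_family:
                    peptide = str(Seq(g.cds).translate()).rstrip("*")
                    fh.write(f">{g.transcript}\n{peptide}\n")
            for taxon in sorted(self.reference_peptides):
                fh.write(f">{taxon}\n{self.reference_peptides[taxon]}\n")


def _allocate_family(config: SimConfig):
    """Deterministic rank layout of tandem clusters, blocks and singletons."""
    n_chrom = config.n_chromosomes
    used: dict[int, set[int]] = {c: set() for c in range(n_chrom)}

    def reserve(chrom: int, ranks: list[int]) -> None:
        if max(ranks) >= config.genes_per_chromosome:
            raise ValueError("config infeasible: rank beyond chromosome")
        if used[chrom] & set(ranks):
            raise ValueError("config infeasible: overlapping structures")
        used[chrom].update(ranks)

    blocks = []
    for k in range(config.n_segmental_blocks):
        ca, cb = k % n_chrom, (k + 1) % n_chrom
        ranks_a = list(range(40, 40 + config.block_anchors))
        ranks_b = list(range(120, 120 + config.block_anchors))
        reserve(ca, ranks_a)
        reserve(cb, ranks_b)
        inverted = k % 2 == 1
        blocks.append((ca, ranks_a, cb, ranks_b, inverted))

    clusters = []
    for i, size in enumerate(config.tandem_cluster_sizes):
        chrom = i % n_chrom
        base = 60 + 15 * (i // n_chrom)
        # odd clusters include one non-family spacer after the first gene
        offsets = ([0] + [j + 1 for j in range(1, size)]) if i % 2 \
            else list(range(size))
        ranks = [base + o for o in offsets]
        reserve(chrom, ranks)
        clusters.append((chrom, ranks))

    n_tandem = sum(config.tandem_cluster_sizes)
    n_block_family = (config.n_segmental_blocks
                      * len(config.family_anchor_offsets) * 2)
    n_singletons = config.family_size - n_tandem - n_block_family
    if n_singletons < 0:
        raise ValueError("config infeasible: family smaller than planted "
                         "structures")
    singletons = []
    for j in range(n_singletons):
        chrom = j % n_chrom
        rank = 150 + 5 * (j // n_chrom)
        reserve(chrom, [rank])
        singletons.append((chrom, rank))
    return blocks, clusters, singletons


def gen_genome(config: SimConfig, seed: int) -> GenomeBundle:
    """Generate the annotation, sequences, hit tables and ground truth."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_chrom = config.n_chromosomes
    chrom_names = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    blocks, clusters, singletons = _allocate_family(config)

    # class anchors: deeply diverged ancestral coding sequences
    ancestors = [_random_cds(rng, config.cds_codons)
                 for _ in range(config.n_classes)]
    ref_peptides = {
        f"REF_{_CLASS_LABELS[i]}":
            str(Seq(anc).translate()).rstrip("*")
        for i, anc in enumerate(ancestors)}
    ref_labels = {name: name.split("_")[1] for name in ref_peptides}

    truth = GroundTruth()
    genes: dict[tuple[int, int], _Gene] = {}

    def locus_name(chrom: int, rank: int) -> str:
        return f"syn{chrom + 1:02d}g{rank:04d}"

    def add_family_gene(chrom: int, rank: int, cds: str,
                        class_idx: int) -> _Gene:
        locus = locus_name(chrom, rank)
        label = _CLASS_LABELS[class_idx]
        gene = _Gene(locus=locus, transcript=f"{locus}.1",
                     chrom=chrom_names[chrom], rank=rank,
                     strand="+" if rank % 2 == 0 else "-",
                     cds=cds, n_exons=5 + class_idx % 4,
                     is_family=True, class_label=label)
        genes[(chrom, rank)] = gene
        truth.family.append(gene.transcript)
        truth.classes[gene.transcript] = label
        return gene

    def derive(ancestor: str, ks: float) -> str:
        n_events = int(rng.poisson(ks * _syn_site_total(ancestor)))
        seq, *_ = _evolve_lineage(ancestor, n_events, config.omega, rng)
        return seq

    # tandem clusters: young duplicates of a shared cluster ancestor
    for i, (chrom, ranks) in enumerate(clusters):
        class_idx = i % config.n_classes
        cluster_anc = derive(ancestors[class_idx],
                             config.within_class_ks / 2)
        for rank in ranks:
            cds = derive(cluster_anc, 0.025)
            gene = add_family_gene(chrom, rank, cds, class_idx)
            truth.tandem.append(gene.transcript)

    # segmental blocks: duplicated segments with interleaved family anchors
    ks_levels = list(config.pair_ks_levels)
    pair_counter = 0
    for k, (ca, ranks_a, cb, ranks_b, inverted) in enumerate(blocks):
        class_idx = k % config.n_classes
        b_ranks = list(reversed(ranks_b)) if inverted else ranks_b
        family_offsets = set(config.family_anchor_offsets)
        for off, (ra, rb) in enumerate(zip(ranks_a, b_ranks)):
            if off in family_offsets:
                ks = ks_levels[pair_counter % len(ks_levels)]
                pair_counter += 1
                base = derive(ancestors[class_idx],
                              config.within_class_ks / 2)
                cds_a, cds_b, _ = evolve_cds_pair(
                    config.cds_codons, ks, config.omega,
                    rng=rng, ancestor=base)
                ga = add_family_gene(ca, ra, cds_a, class_idx)
                gb = add_family_gene(cb, rb, cds_b, class_idx)
                truth.segmental.extend([ga.transcript, gb.transcript])
                from .duplication import assign_wgd_bin
                truth.collinear_pairs.append(
                    (ga.transcript, gb.transcript, ks, assign_wgd_bin(ks)))

    # singleton family members
    for j, (chrom, rank) in enumerate(singletons):
        class_idx = j % config.n_classes
        cds = derive(ancestors[class_idx], config.within_class_ks / 2)
        add_family_gene(chrom, rank, cds, class_idx)

    # background (non-family) genes fill every remaining rank
    for chrom in range(n_chrom):
        for rank in range(config.genes_per_chromosome):
            if (chrom, rank) in genes:
                continue
            n_codons = int(rng.integers(150, 400))
            locus = locus_name(chrom, rank)
            genes[(chrom, rank)] = _Gene(
                locus=locus, transcript=f"{locus}.1",
                chrom=chrom_names[chrom], rank=rank,
                strand="+" if rank % 2 == 0 else "-",
                cds=_random_cds(rng, n_codons),
                n_exons=int(rng.integers(1, 10)))

    gene_list = [genes[key] for key in sorted(genes)]
    family_genes = [g for g in gene_list if g.is_family]

    # one multi-transcript family locus: a shorter second qualifying mRNA
    multi = family_genes[0]
    short = _Gene(locus=multi.locus, transcript=f"{multi.locus}.2",
                  chrom=multi.chrom, rank=multi.rank, strand=multi.strand,
                  cds=multi.cds[:3 * (config.cds_codons - 51)] + "TAA",
                  n_exons=multi.n_exons, is_family=False)
    extra_transcripts = [short]

    # domain hits: full three-domain signature for family members,
    # decoys with partial signatures / weak hits / broken ORFs
    peptide_len = config.cds_codons - 1
    dom_spans = {"Cu-oxidase": (10, 140), "Cu-oxidase_2": (150, 230),
                 "Cu-oxidase_3": (240, min(290, peptide_len))}
    rows = []

    def add_hits(transcript: str, domains, evalue: float) -> None:
        for dom in domains:
            lo, hi = dom_spans[dom]
            rows.append({"gene_id": transcript, "domain": dom,
                         "e_value": evalue * float(rng.uniform(0.5, 2.0)),
                         "qstart": lo, "qend": hi})

    for g in family_genes:
        add_hits(g.transcript, dom_spans, 1e-40)
    add_hits(short.transcript, dom_spans, 1e-35)

    non_family = [g for g in gene_list if not g.is_family]
    decoy_pool = [g for g in non_family if g.rank >= 200]
    partial = decoy_pool[:15]
    weak = decoy_pool[15:25]
    broken = decoy_pool[25:30]
    for i, g in enumerate(partial):
        doms = list(dom_spans)[:1 + i % 2]
        add_hits(g.transcript, doms, 1e-20)
    for g in weak:
        add_hits(g.transcript, dom_spans, 1e-3)  # above the 1e-5 ceiling
    for g in broken:
        g.cds = "CTG" + g.cds[3:]  # destroy the start codon
        add_hits(g.transcript, dom_spans, 1e-30)
    domain_hits = pd.DataFrame(rows)

    # homolog hits: block anchors, tandem pairs, random background
    hrows = []
    for k, (ca, ranks_a, cb, ranks_b, inverted) in enumerate(blocks):
        b_ranks = list(reversed(ranks_b)) if inverted else ranks_b
        for ra, rb in zip(ranks_a, b_ranks):
            hrows.append({
                "query": genes[(ca, ra)].transcript,
                "subject": genes[(cb, rb)].transcript,
                "evalue": 1e-50 * float(rng.uniform(0.1, 10)),
                "bitscore": float(rng.uniform(380, 520))})
    for chrom, ranks in clusters:
        for ra, rb in zip(ranks, ranks[1:]):
            hrows.append({
                "query": genes[(chrom, ra)].transcript,
                "subject": genes[(chrom, rb)].transcript,
                "evalue": 1e-80, "bitscore": float(rng.uniform(500, 600))})
    all_ids = [g.transcript for g in gene_list]
    for _ in range(150):
        qi, si = rng.integers(0, len(all_ids), size=2)
        if qi == si:
            continue
        hrows.append({"query": all_ids[qi], "subject": all_ids[si],
                      "evalue": float(10.0 ** rng.uniform(-30, -2)),
                      "bitscore": float(rng.uniform(40, 120))})
    homolog_hits = pd.DataFrame(hrows)

    truth.family.sort()
    truth.tandem.sort()
    truth.segmental = sorted(set(truth.segmental))
    return GenomeBundle(config=config, genes=gene_list,
                        extra_transcripts=extra_transcripts,
                        domain_hits=domain_hits, homolog_hits=homolog_hits,
                        truth=truth, reference_peptides=ref_peptides,
                        reference_labels=ref_labels)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def gen_expression(
    config: SimConfig,
    seed: int,
    gene_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Tissue FPKM and infection time-course tables with planted classes.

    Tissue classes: constitutive (every tissue near a level >= 3x the
    grand mean), specific (one dominant tissue, tau >= 0.9 by
    construction), inactive (< 1 FPKM everywhere), moderate (the rest).
    Response classes: induced / suppressed (|log2 change| >= 2 at >= 1
    post-infection timepoint) and unchanged.
    """
    config.validate()
    n_genes = len(gene_ids)
    planted = config.n_constitutive + config.n_specific + config.n_inactive
    if planted > n_genes:
        raise ValueError("expression class mix exceeds the gene count")
    rng = np.random.default_rng(seed)
    tissues = list(config.tissues)
    n_t = len(tissues)
    sigma = config.expr_noise_sigma

    order = rng.permutation(n_genes)
    labels = np.array(["moderate"] * n_genes, dtype=object)
    labels[order[:config.n_constitutive]] = "constitutive"
    labels[order[config.n_constitutive:
                 config.n_constitutive + config.n_specific]] = "specific"
    labels[order[config.n_constitutive + config.n_specific:planted]] = \
        "inactive"

    base = np.zeros((n_genes, n_t))
    spec_i = 0
    for i, label in enumerate(labels):
        if label == "moderate":
            level = float(rng.lognormal(np.log(5.0), 0.4))
            base[i] = level * rng.lognormal(0.0, 0.6, n_t)
        elif label == "specific":
            tissue = spec_i % n_t
            spec_i += 1
            base[i] = rng.lognormal(np.log(0.4), 0.4, n_t)
            base[i, tissue] = rng.lognormal(np.log(60.0), 0.3)
        elif label == "inactive":
            base[i] = rng.uniform(0.01, 0.4, n_t)
    # constitutive floor solved so every planted tissue value is >= 3.5x
    # the final grand mean (pre-noise); jitter only scales upward
    rest_sum = base.sum()
    n_high = config.n_constitutive
    fold, jitter_mean = 3.5, 1.15
    grand = rest_sum / (n_t * (n_genes - n_high * fold * jitter_mean))
    level = fold * grand
    for i, label in enumerate(labels):
        if label == "constitutive":
            base[i] = level * rng.uniform(1.0, 1.3, n_t)
    tissue_df = pd.DataFrame(
        base * rng.lognormal(0.0, sigma, base.shape),
        index=pd.Index(gene_ids, name="gene_id"), columns=tissues).round(4)

    # infection time course
    n_resp = config.n_induced + config.n_suppressed
    if n_resp > n_genes:
        raise ValueError("response class mix exceeds the gene count")
    rorder = rng.permutation(n_genes)
    rlabels = np.array(["unchanged"] * n_genes, dtype=object)
    rlabels[rorder[:config.n_induced]] = "induced"
    rlabels[rorder[config.n_induced:n_resp]] = "suppressed"

    n_post = len(config.timepoints) - 1
    tc = np.zeros((n_genes, n_post + 1))
    for i, label in enumerate(rlabels):
        if label == "unchanged":
            x0 = float(rng.lognormal(np.log(4.0), 0.8))
            tc[i, 0] = x0
            tc[i, 1:] = x0 * 2.0 ** rng.normal(0.0, 0.2, n_post)
        elif label == "induced":
            x0 = float(rng.lognormal(np.log(2.0), 0.4))
            tc[i, 0] = x0
            folds = 2.0 ** rng.uniform(0.2, 0.8, n_post)
            peak = int(rng.integers(0, n_post))
            folds[peak] = 2.0 ** rng.uniform(2.0, 3.5)
            tc[i, 1:] = x0 * folds
        else:
            x0 = float(rng.lognormal(np.log(10.0), 0.4))
            tc[i, 0] = x0
            folds = 2.0 ** -rng.uniform(0.2, 0.8, n_post)
            dip = int(rng.integers(0, n_post))
            folds[dip] = 2.0 ** -rng.uniform(2.0, 3.5)
            tc[i, 1:] = x0 * folds
    tc_df = pd.DataFrame(tc, index=pd.Index(gene_ids, name="gene_id"),
                         columns=list(config.timepoints)).round(4)

    truth = GroundTruth(
        tissue_labels={g: l for g, l in zip(gene_ids, labels)},
        response_labels={g: l for g, l in zip(gene_ids, rlabels)})
    return tissue_df, tc_df, truth


# ---------------------------------------------------------------------------
# Two-population genotype panel
# ---------------------------------------------------------------------------

def _dosage_to_alleles(dosage: np.ndarray) -> np.ndarray:
    a1 = (dosage > 1).astype(np.int8)
    a2 = (dosage > 0).astype(np.int8)
    return np.stack([a1, a2], axis=-1)


def gen_population(
    config: SimConfig,
    seed: int,
    gene_ids: list[str] | None = None,
) -> tuple[VariantTable, pd.DataFrame, GroundTruth]:
    """Two-population genotypes with planted low-diversity sweep regions.

    Wild allele frequencies are Beta(b, b)-distributed (U-shaped, a
    neutral-like site-frequency spectrum); cultivated frequencies follow
    a drift kernel Beta(p*k, (1-p)*k) emulating the domestication
    bottleneck, and inside sweep regions an extra fixation step removes
    a fraction 1 - 1/reduction of the remaining heterozygosity.  One
    designated sweep gene sits at the centre of each region; all other
    genes are placed at least 20 kb away from any region.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    chroms = [f"pchr{c + 1}" for c in range(config.pop_n_chromosomes)]
    length = config.pop_chrom_length
    span = config.sweep_span

    regions: list[tuple[str, int, int]] = []
    for i in range(config.n_sweep_regions):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(0, length))
        if start + span > length:
            log.warning("sweep region beyond chromosome end; clipped")
            start = length - span
        if start < int(0.1 * length):
            start = int(0.1 * length)
        regions.append((chrom, start, start + span))

    # genes: one at each sweep centre, the rest kept clear of the regions
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:03d}" for i in range(90)]
    if len(gene_ids) < config.n_sweep_regions:
        raise ValueError("fewer genes than sweep regions")
    gene_rows = []
    sweep_genes = []
    for (chrom, start, end), gid in zip(regions, gene_ids):
        mid = (start + end) // 2
        gene_rows.append((gid, chrom, mid - config.gene_span // 2,
                          mid + config.gene_span // 2))
        sweep_genes.append(gid)
    buffer = 20_000
    for gid in gene_ids[config.n_sweep_regions:]:
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, length - config.gene_span))
            clear = all(not (chrom == rc and start < re + buffer
                             and start + config.gene_span > rs - buffer)
                        for rc, rs, re in regions)
            if clear:
                gene_rows.append((gid, chrom, start,
                                  start + config.gene_span))
                break
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chromosome", "start", "end"])

    n_w, n_c = config.n_wild, config.n_cultivated
    samples = [f"W{i + 1:03d}" for i in range(n_w)] \
        + [f"C{i + 1:03d}" for i in range(n_c)]
    populations = {s: ("wild" if s.startswith("W") else "cultivated")
                   for s in samples}

    all_chrom, all_pos, all_gt = [], [], []
    refs, alts = [], []
    nuc_pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    for chrom in chroms:
        n_sites = int(round(length * config.snp_density))
        pos = np.unique(rng.integers(1, length + 1, size=n_sites))
        n = len(pos)
        b = config.wild_beta_shape
        p_w = np.clip(rng.beta(b, b, n), 1e-6, 1 - 1e-6)
        k = config.bottleneck_k
        p_c = rng.beta(p_w * k, (1 - p_w) * k)
        in_sweep = np.zeros(n, dtype=bool)
        for rc, rs, re in regions:
            if rc == chrom:
                in_sweep |= (pos - 1 >= rs) & (pos - 1 < re)
        fix = in_sweep & (rng.random(n) < 1.0 - 1.0 / config.sweep_reduction)
        p_c = np.where(fix, rng.binomial(1, p_c).astype(float), p_c)
        dosage = np.empty((n, n_w + n_c), dtype=np.int8)
        dosage[:, :n_w] = rng.binomial(2, p_w[:, None], size=(n, n_w))
        dosage[:, n_w:] = rng.binomial(2, p_c[:, None], size=(n, n_c))
        gt = _dosage_to_alleles(dosage)
        rate = np.full(n, config.missing_rate)
        rate[rng.random(n) < config.high_missing_fraction] = \
            config.high_missing_rate
        miss = rng.random((n, n_w + n_c)) < rate[:, None]
        gt[miss] = -1
        pair_idx = rng.integers(0, len(nuc_pairs), size=n)
        all_chrom.append(np.full(n, chrom))
        all_pos.append(pos)
        all_gt.append(gt)
        refs.append(np.array([nuc_pairs[i][0] for i in pair_idx]))
        alts.append(np.array([nuc_pairs[i][1] for i in pair_idx]))

    table = VariantTable(
        chrom=np.concatenate(all_chrom), pos=np.concatenate(all_pos),
        ref=np.concatenate(refs), alt=np.concatenate(alts),
        genotypes=np.concatenate(all_gt), samples=samples,
        populations=populations)
    truth = GroundTruth(sweep_regions=regions, sweep_genes=sweep_genes)
    return table, genes, truth


def chrom_lengths(config: SimConfig) -> dict[str, int]:
    return {f"pchr{c + 1}": config.pop_chrom_length
            for c in range(config.pop_n_chromosomes)}


# ---------------------------------------------------------------------------
# Writers for the population bundle
# ---------------------------------------------------------------------------

_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_vcf(table: VariantTable, path: str,
              lengths: dict[str, int] | None = None) -> None:
    gt = table.genotypes
    code = np.where((gt < 0).any(axis=2), 3, gt.sum(axis=2))
    strings = _GT_STRINGS[code]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in dict.fromkeys(table.chrom):
            ln = (lengths or {}).get(chrom)
            if ln:
                fh.write(f"##contig=<ID={chrom},length={ln}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}"
                     f"\t{table.alt[i]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(strings[i]) + "\n")


def write_population_table(populations: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tpopulation\n")
        for acc, pop in populations.items():
            fh.write(f"{acc}\t{pop}\n")


def write_gene_bed(genes: pd.DataFrame, path: str) -> None:
    genes[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def validate_bundle(bundle: GenomeBundle) -> list[str]:
    """Cross-check ground truth against the emitted tables."""
    issues = []
    fam = set(bundle.truth.family)
    with_domains = bundle.domain_hits[
        bundle.domain_hits["e_value"] <= 1e-5].groupby("gene_id")["domain"] \
        .agg(set)
    three = {g for g, doms in with_domains.items() if len(doms) == 3}
    missing = fam - three
    if missing:
        issues.append(f"family members without full domain signature: "
                      f"{sorted(missing)[:5]}")
    order = bundle.gene_order()
    for a, b, _ks, _bin in bundle.truth.collinear_pairs:
        if a not in order or b not in order:
            issues.append(f"collinear pair {a}/{b} missing from gene order")
    hits = set(zip(bundle.homolog_hits["query"],
                   bundle.homolog_hits["subject"]))
    for a, b, _ks, _bin in bundle.truth.collinear_pairs:
        if (a, b) not in hits and (b, a) not in hits:
            issues.append(f"collinear pair {a}/{b} missing from homologs")
    return issues
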