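"""Duplication analysis: collinear block detection, tandem/segmental
classification, Nei–Gojobori Ka/Ks, WGD-event binning and molecular dating.

The Ka/Ks estimator is the classical NG86 counting method: per-codon
synonymous/nonsynonymous site fractions, differences averaged with equal
weight over all minimal mutational pathways between differing codons, and
a Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) for multiple hits.

Synonymous divergence dates duplications against the three rounds of
whole-genome duplication in the soybean lineage: the *Glycine* genus event
(Ks < 0.3, ~13 Mya), the legume event (0.3 <= Ks < 1.5, ~58 Mya) and the
ancient gamma event (Ks >= 1.5).  T = Ks / (2 lambda) converts synonymous
divergence to time under a clock rate lambda (default 6.1e-9 substitutions
per synonymous site per year).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

LAMBDA_RATE = 6.1e-9  # synonymous substitutions per site per year

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    ka: float
    ks: float
    omega: float  # nan when Ks == 0
    sd: float     # synonymous differences
    nd: float     # nonsynonymous differences
    s_sites: float
    n_sites: float
    n_codons: int


class SaturationWarning(UserWarning):
    pass


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """NG86 synonymous site count of a sense codon.

    Each position contributes (synonymous one-step neighbours)/3; changes
    producing a stop codon count as nonsynonymous.
    """
    aa = _aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) step counts over minimal pathways.

    Pathways passing through a stop codon are excluded; in the degenerate
    case where every ordering is blocked, all orderings are used with the
    stop treated as a distinct residue (every step through it nonsynonymous).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS and not allow_stops:
                return None
            sd_step = _aa(current) == _aa(nxt)
            sd += sd_step
            nd += not sd_step
            current = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    results = [r for o in orders if (r := walk(o, False)) is not None]
    if not results:
        results = [walk(o, True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _usable(codon: str) -> bool:
    return (len(codon) == 3 and all(c in _NUCS for c in codon)
            and codon not in _STOPS)


def _jukes_cantor(p: float, which: str) -> float:
    if p >= 0.75:
        log.warning("%s proportion %.4f >= 3/4: saturated, distance infinite",
                    which, p)
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka, Ks and omega for an in-frame, gap-free codon alignment.

    Codons containing gaps, ambiguity characters or stops in either
    sequence are skipped pairwise.  A saturated rate (p >= 3/4) is
    reported as infinity with a warning; omega is NaN when Ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValueError("alignment length not divisible by 3")

    s_a = s_b = sd = nd = 0.0
    used = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if not (_usable(ca) and _usable(cb)):
            continue
        used += 1
        s_a += _syn_sites(ca)
        s_b += _syn_sites(cb)
        dsd, dnd = _pathway_differences(ca, cb)
        sd += dsd
        nd += dnd
    if used == 0:
        raise ValueError("no usable codons in the alignment")

    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * used - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps, "synonymous") if sd > 0 else 0.0
    ka = _jukes_cantor(pn, "nonsynonymous") if nd > 0 else 0.0
    if ks == 0.0:
        omega = math.nan
    elif math.isinf(ks):
        omega = 0.0 if not math.isinf(ka) else math.nan
    else:
        omega = ka / ks
    return KaKsResult(ka=ka, ks=ks, omega=omega, sd=sd, nd=nd,
                      s_sites=s_sites, n_sites=n_sites, n_codons=used)


# ---------------------------------------------------------------------------
# WGD binning and dating
# ---------------------------------------------------------------------------

#: Half-open Ks bins, youngest first; a boundary belongs to the older event.
WGD_BINS = (("glycine", 0.0, 0.3), ("legume", 0.3, 1.5),
            ("gamma", 1.5, math.inf))


def assign_wgd_bin(ks: float) -> str:
    """Map a pair's Ks to the WGD event it most plausibly dates from."""
    if ks < 0:
        raise ValueError("negative Ks")
    for name, lo, hi in WGD_BINS:
        if lo <= ks < hi:
            return name
    return WGD_BINS[-1][0]


def date_duplication(ks: float, lambda_rate: float = LAMBDA_RATE) -> float:
    """Divergence time T = Ks / (2 lambda), in million years."""
    if lambda_rate <= 0:
        raise ValueError("lambda must be positive")
    if ks < 0:
        raise ValueError("negative Ks")
    return ks / (2.0 * lambda_rate) / 1e6


# ---------------------------------------------------------------------------
# Collinear (synteny) blocks
# ---------------------------------------------------------------------------

@dataclass
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenyBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # same | inverted
    anchors: list[Anchor]

    def __post_init__(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError("block anchors not strictly increasing in A")
        ok = (all(y > x for x, y in zip(rb, rb[1:]))
              if self.orientation == "same"
              else all(y < x for x, y in zip(rb, rb[1:])))
        if not ok:
            raise ValueError("block anchors not strictly monotone in B")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)


def read_gene_order(path: str) -> dict[str, tuple[str, int]]:
    """Read `gene_id  chromosome  rank` into gene -> (chromosome, rank)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return {row.gene_id: (row.chromosome, int(row.rank))
            for row in df.itertuples()}


def read_homolog_hits(path: str) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    required = {"query", "subject", "evalue", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return hits


def _best_chain(
    anchors: list[Anchor], orientation: str, max_gap: int
) -> list[int]:
    """Indices of the best monotone chain: longest, ties by summed score."""
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    n = len(order)
    best_len = [1] * n
    best_score = [anchors[order[i]].score for i in range(n)]
    prev = [-1] * n
    for i in range(n):
        ai = anchors[order[i]]
        for j in range(i):
            aj = anchors[order[j]]
            da = ai.rank_a - aj.rank_a
            if not (0 < da <= max_gap):
                continue
            db = (ai.rank_b - aj.rank_b if orientation == "same"
                  else aj.rank_b - ai.rank_b)
            if not (0 < db <= max_gap):
                continue
            cand = (best_len[j] + 1, best_score[j] + ai.score)
            if cand > (best_len[i], best_score[i]):
                best_len[i], best_score[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], best_score[i]))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def detect_blocks(
    hits: pd.DataFrame,
    gene_order: dict[str, tuple[str, int]],
    min_anchors: int = 5,
    max_rank_gap: int = 25,
    evalue_max: float = 1e-5,
) -> list[SyntenyBlock]:
    """Chain homology hits into collinear blocks by gene rank.

    Within each chromosome pair, hits are chained by the longest strictly
    monotone chain (dynamic programming) whose consecutive anchors are at
    most ``max_rank_gap`` ranks apart in both genomes, in either the same
    or the inverted orientation.  The best chain (longest; ties by summed
    bit score) is extracted, its anchors retired, and chaining repeats
    while chains of at least ``min_anchors`` anchors remain.
    """
    missing = sorted({g for g in pd.concat([hits["query"], hits["subject"]])
                      if g not in gene_order})
    if missing:
        raise ValueError(f"hits reference genes missing from the gene order: "
                         f"{', '.join(missing[:10])}")

    pair_best: dict[tuple[str, str], Anchor] = {}
    for row in hits.itertuples():
        if row.evalue > evalue_max or row.query == row.subject:
            continue
        ca, ra = gene_order[row.query]
        cb, rb = gene_order[row.subject]
        ga, gb = row.query, row.subject
        if (ca, ra) > (cb, rb):  # canonical orientation
            ca, cb, ra, rb, ga, gb = cb, ca, rb, ra, gb, ga
        if ca == cb and ra == rb:
            continue
        key = (ga, gb)
        if key not in pair_best or row.bitscore > pair_best[key].score:
            pair_best[key] = Anchor(ga, gb, ra, rb, float(row.bitscore))

    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for (ga, gb), anchor in pair_best.items():
        grouped.setdefault((gene_order[ga][0], gene_order[gb][0]),
                           []).append(anchor)

    blocks: list[SyntenyBlock] = []
    block_id = 0
    for (ca, cb) in sorted(grouped):
        pool = grouped[(ca, cb)]
        while len(pool) >= min_anchors:
            candidates = []
            for orientation in ("same", "inverted"):
                chain = _best_chain(pool, orientation, max_rank_gap)
                sc = sum(pool[i].score for i in chain)
                candidates.append((len(chain), sc, orientation, chain))
            length, _sc, orientation, chain = max(candidates,
                                                  key=lambda c: c[:2])
            if length < min_anchors:
                break
            chosen = [pool[i] for i in chain]
            block_id += 1
            blocks.append(SyntenyBlock(block_id, ca, cb, orientation, chosen))
            taken = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in taken]
    return blocks


def classify_tandem(
    catalog_order: dict[str, list[str]],
    family_members: set[str],
    max_spacers: int = 1,
) -> set[str]:
    """Family members in tandem clusters (<= ``max_spacers`` genes between).

    ``catalog_order`` gives the full genome gene order per chromosome
    (family and non-family alike); two members are linked iff they lie on
    one chromosome with at most one non-family gene between them, and the
    tandem set is the union of linked clusters of size >= 2.
    """
    tandem: set[str] = set()
    for genes in catalog_order.values():
        positions = [(i, g) for i, g in enumerate(genes)
                     if g in family_members]
        cluster: list[str] = []
        last = None
        for idx, gene in positions:
            if last is not None and idx - last <= max_spacers + 1:
                cluster.append(gene)
            else:
                if len(cluster) >= 2:
                    tandem.update(cluster)
                cluster = [gene]
            last = idx
        if len(cluster) >= 2:
            tandem.update(cluster)
    return tandem


def classify_segmental(
    blocks: list[SyntenyBlock],
    family_members: set[str],
) -> tuple[set[str], list[tuple[str, str]]]:
    """Family members anchored to another family member in a block.

    Returns the segmental member set and the collinear family pairs
    (sorted, deduplicated anchor pairs with both genes in the family).
    """
    segmental: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for block in blocks:
        for anchor in block.anchors:
            if anchor.gene_a in family_members and \
                    anchor.gene_b in family_members:
                segmental.update((anchor.gene_a, anchor.gene_b))
                pairs.add(tuple(sorted((anchor.gene_a, anchor.gene_b))))
    return segmental, sorted(pairs)


# ---------------------------------------------------------------------------
# Summaries and IO
# ---------------------------------------------------------------------------

def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def summarize_duplication(
    wgd_bins: list[str],
    tandem: set[str],
    segmental: set[str],
    family_size: int,
) -> pd.DataFrame:
    """Per-bin pair counts/percentages and tandem/segmental percentages."""
    n_pairs = len(wgd_bins)
    rows = []
    for name, _lo, _hi in WGD_BINS:
        count = sum(1 for b in wgd_bins if b == name)
        rows.append({"metric": f"wgd_{name}", "count": count,
                     "denominator": n_pairs, "percent": _pct(count, n_pairs)})
    rows.append({"metric": "tandem", "count": len(tandem),
                 "denominator": family_size,
                 "percent": _pct(len(tandem), family_size)})
    rows.append({"metric": "segmental", "count": len(segmental),
                 "denominator": family_size,
                 "percent": _pct(len(segmental), family_size)})
    return pd.DataFrame(rows)


def analyze_pairs(
    pairs: list[tuple[str, str]],
    cds: dict[str, str],
    lambda_rate: float = LAMBDA_RATE,
) -> pd.DataFrame:
    """Ka/Ks, WGD bin and age for each collinear gene pair."""
    rows = []
    for gene_a, gene_b in pairs:
        res = ng86_kaks(cds[gene_a], cds[gene_b])
        rows.append({
            "gene_a": gene_a, "gene_b": gene_b,
            "ka": res.ka, "ks": res.ks, "omega": res.omega,
            "wgd_bin": assign_wgd_bin(res.ks) if math.isfinite(res.ks)
                       else "gamma",
            "T_mya": date_duplication(res.ks, lambda_rate)
                     if math.isfinite(res.ks) else math.inf,
        })
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "ka", "ks", "omega",
                       "wgd_bin", "T_mya"])


def write_blocks(blocks: list[SyntenyBlock], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("block_id\tchrom_a\tchrom_b\torientation\t"
                     "gene_a\tgene_b\trank_a\trank_b\tbitscore\n")
        for block in blocks:
            for a in block.anchors:
                handle.write(f"{block.block_id}\t{block.chrom_a}\t"
                             f"{block.chrom_b}\t{block.orientation}\t"
                             f"{a.gene_a}\t{a.gene_b}\t{a.rank_a}\t"
                             f"{a.rank_b}\t{a.score:g}\n")


def read_blocks(path: str) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    blocks = []
    for bid, sub in df.groupby("block_id", sort=True):
        first = sub.iloc[0]
        anchors = [Anchor(r.gene_a, r.gene_b, int(r.rank_a), int(r.rank_b),
                          float(r.bitscore)) for r in sub.itertuples()]
        blocks.append(SyntenyBlock(int(bid), first["chrom_a"],
                                   first["chrom_b"], first["orientation"],
                                   anchors))
    return blocks
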