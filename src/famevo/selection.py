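"""Two-population nucleotide-diversity scan for domestication sweeps.

Workflow: biallelic SNPs are filtered on missingness and minor allele
frequency (over the combined panel), per-window nucleotide diversity (pi)
is computed separately for the wild and the cultivated population in
sliding windows (default 20 kb windows, 10 kb step), and the per-window
ratio pi_cultivated / pi_wild is compared against its chromosome mean and
against the genome-wide lowest-5% tail.  Genes overlapping bottom-tail
windows are called as selective-sweep candidates: a domesticated
population loses diversity precisely where selection acted.

Per-site diversity uses the unbiased estimator
h = n/(n-1) * (1 - p^2 - q^2) over the n called alleles; window pi divides
the summed h by the full window span in bp, so monomorphic positions count
as zero diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import phylogeny

log = logging.getLogger(__name__)

WINDOW_SIZE = 20_000
WINDOW_STEP = 10_000
MAX_MISSING = 0.10
MIN_MAF = 0.05
SWEEP_QUANTILE = 0.05

POPULATIONS = ("wild", "cultivated")


@dataclass
class VariantTable:
    """Biallelic SNP genotypes with population labels.

    ``genotypes`` has shape (n_sites, n_samples, 2) with allele codes
    0 (ref), 1 (alt) and -1 (missing).  Positions are 1-based and strictly
    increasing within a chromosome.
    """

    chrom: np.ndarray       # str per site
    pos: np.ndarray         # int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray   # int8 (n_sites, n_samples, 2)
    samples: list[str]
    populations: dict[str, str]  # sample -> wild | cultivated

    def __post_init__(self) -> None:
        for chrom in np.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if (np.diff(p) <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.populations.get(s) == population]
        if not idx:
            raise ValueError(f"no samples in population {population!r}")
        return np.array(idx)

    def subset_sites(self, keep: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[keep], self.pos[keep],
                            self.ref[keep], self.alt[keep],
                            self.genotypes[keep], list(self.samples),
                            dict(self.populations))


def read_population_table(path: str) -> dict[str, str]:
    """Read `accession  population` (wild | cultivated)."""
    pops = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            acc, _, pop = line.partition("\t")
            if acc == "accession" and pop == "population":
                continue
            if pop not in POPULATIONS:
                raise ValueError(f"{path}: unknown population {pop!r}")
            pops[acc] = pop
    return pops


def read_vcf(path: str, populations: dict[str, str]) -> VariantTable:
    """Load biallelic SNPs from a VCF; other sites are dropped with a warning."""
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, gts = [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        arr = np.array([g[:2] for g in v.genotypes], dtype=np.int8)
        if (arr > 1).any():
            n_dropped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(arr)
    if n_dropped:
        log.warning("%s: dropped %d non-biallelic-SNP records",
                    path, n_dropped)
    return VariantTable(
        chrom=np.array(chroms), pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs), alt=np.array(alts),
        genotypes=np.array(gts, dtype=np.int8),
        samples=samples, populations=dict(populations))


def filter_variants(
    table: VariantTable,
    max_missing: float = MAX_MISSING,
    min_maf: float = MIN_MAF,
) -> VariantTable:
    """Drop sites with too much missing data or too rare a minor allele.

    Both statistics are computed over the combined two-population panel:
    missing fraction over allele calls must be <= ``max_missing`` and the
    minor allele frequency over called alleles must be >= ``min_maf``.
    """
    gt = table.genotypes
    called = gt >= 0
    n_total = gt.shape[1] * 2
    n_called = called.sum(axis=(1, 2))
    missing_frac = 1.0 - n_called / n_total
    alt_count = ((gt == 1) & called).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_count / n_called, 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (missing_frac <= max_missing) & (maf >= min_maf)
    log.info("variant filter kept %d of %d sites", int(keep.sum()),
             table.n_sites)
    return table.subset_sites(keep)


def make_windows(
    chrom_length: int,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[tuple[int, int]]:
    """Half-open sliding windows [k*step, k*step+size) truncated at the end."""
    if size < step:
        raise ValueError("window size < step would leave gaps between windows")
    windows = []
    start = 0
    while start < chrom_length:
        windows.append((start, min(start + size, chrom_length)))
        start += step
    return windows


def _site_heterozygosity(gt: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity over called alleles (0 if n < 2)."""
    called = gt >= 0
    n = called.sum(axis=(1, 2)).astype(float)
    alt = ((gt == 1) & called).sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
        h = n / np.maximum(n - 1.0, 1e-300) * (1.0 - p ** 2 - (1.0 - p) ** 2)
    h[n < 2] = 0.0
    return h


def window_pi(
    table: VariantTable,
    population: str,
    windows_by_chrom: dict[str, list[tuple[int, int]]],
) -> pd.DataFrame:
    """Per-window nucleotide diversity (per bp) for one population."""
    idx = table.sample_indices(population)
    h = _site_heterozygosity(table.genotypes[:, idx, :])
    rows = []
    for chrom, windows in windows_by_chrom.items():
        on_chrom = table.chrom == chrom
        pos0 = table.pos[on_chrom] - 1  # to 0-based bp
        h_chrom = h[on_chrom]
        for start, end in windows:
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            span = end - start
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_snps": int(hi - lo),
                "pi": float(h_chrom[lo:hi].sum()) / span,
            })
    return pd.DataFrame(rows)


def ratio_scan(pi_wild: pd.DataFrame, pi_cult: pd.DataFrame) -> pd.DataFrame:
    """Join the two scans and compute ratio = pi_cult / pi_wild per window.

    Windows with pi_wild = 0 get a null ratio and are excluded from any
    ranking downstream.
    """
    keys = ["chrom", "start", "end"]
    if not pi_wild[keys].equals(pi_cult[keys]):
        raise ValueError("window lists differ between populations")
    out = pi_wild.rename(columns={"pi": "pi_wild"}).copy()
    out["pi_cult"] = pi_cult["pi"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(out["pi_wild"] > 0,
                         out["pi_cult"] / out["pi_wild"], np.nan)
    out["ratio"] = ratio
    return out[["chrom", "start", "end", "n_snps",
                "pi_wild", "pi_cult", "ratio"]]


def read_gene_bed(path: str) -> pd.DataFrame:
    """Read a BED file (chrom, start, end, name) of gene spans."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "gene_id"],
                     dtype={"chromosome": str})
    return df[["gene_id", "chromosome", "start", "end"]]


def _overlapping_ratios(scan: pd.DataFrame, chrom: str,
                        start: int, end: int) -> np.ndarray:
    sub = scan[(scan["chrom"] == chrom) & (scan["start"] < end)
               & (scan["end"] > start)]
    return sub["ratio"].to_numpy(dtype=float)


def chromosome_baseline(
    scan: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Flag genes whose region ratio falls below their chromosome's mean.

    A gene's region ratio is the mean ratio of the windows overlapping its
    span; the baseline is the arithmetic mean of the chromosome's defined
    window ratios.
    """
    chrom_means = scan.groupby("chrom")["ratio"].mean()
    rows = []
    for gene in genes.itertuples():
        if gene.chromosome not in chrom_means.index or \
                np.isnan(chrom_means[gene.chromosome]):
            raise ValueError(
                f"{gene.gene_id}: no defined windows on {gene.chromosome}")
        ratios = _overlapping_ratios(scan, gene.chromosome,
                                     gene.start, gene.end)
        region = float(np.nanmean(ratios)) if len(ratios) and \
            not np.isnan(ratios).all() else np.nan
        mean = float(chrom_means[gene.chromosome])
        rows.append({
            "gene_id": gene.gene_id, "chromosome": gene.chromosome,
            "start": gene.start, "end": gene.end,
            "region_ratio": region, "chrom_mean": mean,
            "below_chromosome_mean": bool(region < mean)
            if not np.isnan(region) else False,
        })
    return pd.DataFrame(rows)


def call_sweeps(
    scan: pd.DataFrame,
    genes: pd.DataFrame,
    quantile: float = SWEEP_QUANTILE,
) -> tuple[pd.DataFrame, float]:
    """Select genes overlapping the lowest-``quantile`` ratio windows.

    The threshold is the k-th smallest defined window ratio genome-wide
    with k = floor(quantile * n), at least 1 — i.e. exactly the "lowest
    5% of windows", an observed value so ties at the threshold are
    included.  Returns the per-gene sweep report and the threshold.
    """
    defined = scan["ratio"].dropna().to_numpy(dtype=float)
    if len(defined) == 0:
        raise ValueError("no windows with a defined ratio")
    if len(defined) < 20:
        log.warning("only %d defined windows; the %g quantile is unstable",
                    len(defined), quantile)
    k = max(1, int(np.floor(quantile * len(defined))))
    threshold = float(np.sort(defined)[k - 1])
    report = chromosome_baseline(scan, genes)
    selected = []
    for gene in report.itertuples():
        ratios = _overlapping_ratios(scan, gene.chromosome,
                                     gene.start, gene.end)
        ratios = ratios[~np.isnan(ratios)]
        selected.append(bool((ratios <= threshold).any()))
    report["top5_selected"] = selected
    return report, threshold


def ibs_distance_matrix(
    table: VariantTable,
    regions: list[tuple[str, int, int]] | None = None,
) -> tuple[list[str], np.ndarray]:
    """1 - identity-by-state distances between accessions.

    Per pair, IBS is averaged over sites where both accessions are fully
    called: 1 - |dosage_i - dosage_j| / 2.  Optionally restricted to the
    given (chrom, start, end) half-open regions.
    """
    keep = np.ones(table.n_sites, dtype=bool)
    if regions is not None:
        keep = np.zeros(table.n_sites, dtype=bool)
        pos0 = table.pos - 1
        for chrom, start, end in regions:
            keep |= (table.chrom == chrom) & (pos0 >= start) & (pos0 < end)
    gt = table.genotypes[keep]
    called = (gt >= 0).all(axis=2)
    dosage = gt.sum(axis=2).astype(float)
    n = len(table.samples)
    D = np.zeros((n, n))
    for i in range(n):
        both = called[:, i][:, None] & called
        shared = both.sum(axis=0)
        if (shared == 0).any():
            j = int(np.argmax(shared == 0))
            raise ValueError(
                f"accessions {table.samples[i]} and {table.samples[j]} "
                f"share no called sites")
        diff = np.abs(dosage[:, i][:, None] - dosage) / 2.0
        diff[~both] = 0.0
        D[i] = diff.sum(axis=0) / shared
    np.fill_diagonal(D, 0.0)
    return list(table.samples), (D + D.T) / 2.0


def accession_tree(
    table: VariantTable,
    gene_regions: list[tuple[str, int, int]] | None = None,
):
    """NJ tree of accessions from allele-sharing distances."""
    samples, D = ibs_distance_matrix(table, gene_regions)
    return phylogeny.nj_tree(D, samples)


def write_scan(scan: pd.DataFrame, path: str) -> None:
    scan.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scan(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
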