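"""Gene catalog construction and family selection by domain architecture.

A gene family is defined here by domain content: a locus belongs to the
family iff at least one of its transcripts carries all required protein
domains (each below an E-value ceiling) and encodes a complete open reading
frame.  For the multicopper oxidase (laccase) family that motivated this
package the required domains are the three Pfam Cu-oxidase domains
(PF00394, PF07731, PF07732); any other three-domain signature can be
supplied instead.

Coordinates are 1-based inclusive in GFF3 on disk, 0-based half-open in
memory, and restored to 1-based in every written output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Canonical domain names of the laccase (multicopper oxidase) signature.
REQUIRED_DOMAINS = ("Cu-oxidase", "Cu-oxidase_2", "Cu-oxidase_3")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Average (isotope-abundance weighted) residue masses in Da, monomer minus
# water; a free peptide adds one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# EMBOSS pKa set (iep); one fixed published table so pI values are
# reproducible across runs.  Exact agreement with other tools' tables
# (e.g. the Bjellqvist set) is not expected.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


class GFFParseError(ValueError):
    """Malformed GFF3 record; message names the offending line number."""


@dataclass
class GeneModel:
    """One transcript model with a link to its parent locus.

    ``start``/``end`` and the exon/CDS intervals are 0-based half-open.
    """

    gene_id: str
    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_spans: list[tuple[int, int]] = field(default_factory=list)
    peptide: str | None = None
    cds: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class FamilyCatalog:
    """Family members (one transcript per locus) and their basic properties."""

    members: list[GeneModel]
    properties: pd.DataFrame  # indexed by gene_id

    @property
    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]

    def to_tsv(self, path: str) -> None:
        out = self.properties.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.2f")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        if chunk and "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def load_annotation(
    gff3_path: str,
    pep_fasta: str | None = None,
    cds_fasta: str | None = None,
) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS records and attach sequences by mRNA id.

    Returns one :class:`GeneModel` per mRNA; all transcripts of a locus are
    retained at this stage (deduplication happens in :func:`select_family`).
    A CDS whose length is not a multiple of three is flagged and left unset.
    """
    loci: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}

    with open(gff3_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, found {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFFParseError(
                    f"{gff3_path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start1 > end1:
                raise GFFParseError(
                    f"{gff3_path}: line {lineno}: start > end"
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GFFParseError(
                        f"{gff3_path}: line {lineno}: gene without ID"
                    )
                loci[gid] = {"chrom": chrom, "start": start, "end": end,
                             "strand": strand}
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise GFFParseError(
                        f"{gff3_path}: line {lineno}: mRNA without ID/Parent"
                    )
                mrnas[mid] = {"locus": parent, "chrom": chrom, "start": start,
                              "end": end, "strand": strand, "exons": [],
                              "cds": []}
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None or parent not in mrnas:
                    raise GFFParseError(
                        f"{gff3_path}: line {lineno}: {ftype} with unknown "
                        f"Parent {parent!r}"
                    )
                key = "exons" if ftype == "exon" else "cds"
                mrnas[parent][key].append((start, end))

    peptides = {}
    if pep_fasta is not None:
        peptides = {rec.id: str(rec.seq).rstrip("*")
                    for rec in SeqIO.parse(pep_fasta, "fasta")}
    cds_seqs = {}
    if cds_fasta is not None:
        cds_seqs = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(cds_fasta, "fasta")}

    genes: list[GeneModel] = []
    for mid, rec in mrnas.items():
        cds = cds_seqs.get(mid)
        if cds is not None and len(cds) % 3 != 0:
            log.warning("%s: CDS length %d not divisible by 3; cds unset",
                        mid, len(cds))
            cds = None
        genes.append(GeneModel(
            gene_id=mid,
            locus_id=rec["locus"],
            chromosome=rec["chrom"],
            start=rec["start"],
            end=rec["end"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds_spans=sorted(rec["cds"]),
            peptide=peptides.get(mid),
            cds=cds,
        ))
    # Loci with no annotated mRNA still appear, as bare models.
    seen_loci = {g.locus_id for g in genes}
    for gid, rec in loci.items():
        if gid not in seen_loci:
            genes.append(GeneModel(gene_id=gid, locus_id=gid,
                                   chromosome=rec["chrom"],
                                   start=rec["start"], end=rec["end"],
                                   strand=rec["strand"]))
    return genes


def has_complete_orf(cds: str | None) -> bool:
    """ATG start, terminal stop, no internal stop, length divisible by 3."""
    if cds is None or len(cds) < 6 or len(cds) % 3 != 0:
        return False
    if not cds.startswith("ATG") or cds[-3:] not in STOP_CODONS:
        return False
    return all(cds[i:i + 3] not in STOP_CODONS
               for i in range(0, len(cds) - 3, 3))


def read_domain_hits(path: str) -> pd.DataFrame:
    """Read a tabular domain-hit file: gene_id, domain, e_value, qstart, qend."""
    hits = pd.read_csv(path, sep="\t")
    required = {"gene_id", "domain", "e_value", "qstart", "qend"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (hits["e_value"] < 0).any():
        raise ValueError(f"{path}: negative E-value")
    return hits


def select_family(
    genes: list[GeneModel],
    hits: pd.DataFrame,
    evalue_max: float = 1e-5,
    required_domains: tuple[str, ...] = REQUIRED_DOMAINS,
) -> FamilyCatalog:
    """Apply the three-domain family rule and deduplicate transcripts.

    A locus is a member iff at least one of its transcripts carries every
    required domain (each hit with E-value <= ``evalue_max``) and has a
    complete ORF.  Among qualifying transcripts of one locus the longest
    peptide wins; ties break to the lexicographically smallest id.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = sorted(set(hits["gene_id"]) - set(by_id))
    if unknown:
        raise ValueError(
            f"domain hits reference unknown gene ids: {', '.join(unknown)}"
        )

    good = hits[hits["e_value"] <= evalue_max]
    domains_by_gene = good.groupby("gene_id")["domain"].agg(set)
    required = set(required_domains)

    qualifying: dict[str, list[GeneModel]] = {}
    for gene in genes:
        doms = domains_by_gene.get(gene.gene_id, set())
        if required <= doms and has_complete_orf(gene.cds):
            qualifying.setdefault(gene.locus_id, []).append(gene)

    members = []
    for locus in sorted(qualifying):
        candidates = qualifying[locus]
        best = min(candidates,
                   key=lambda g: (-(len(g.peptide or "")), g.gene_id))
        members.append(best)

    rows = {}
    for g in members:
        if g.peptide:
            length, mw, pi = protein_properties(g.peptide)
        else:
            length, mw, pi = 0, math.nan, math.nan
        rows[g.gene_id] = {
            "chromosome": g.chromosome,
            "start": g.start + 1,  # back to 1-based for reporting
            "end": g.end,
            "strand": g.strand,
            "length_aa": length,
            "mw_da": mw,
            "pi": pi,
            "exons": g.n_exons,
        }
    props = pd.DataFrame.from_dict(rows, orient="index")
    props.index.name = "gene_id"
    return FamilyCatalog(members=members, properties=props)


def chromosome_distribution(
    catalog: FamilyCatalog | pd.DataFrame,
    scaffold_prefix: str = "scaffold",
) -> tuple[pd.Series, pd.Series]:
    """Per-chromosome member counts; scaffold-placed members reported apart."""
    if isinstance(catalog, FamilyCatalog):
        chroms = catalog.properties["chromosome"]
    else:
        chroms = catalog["chromosome"]
    counts = chroms.value_counts().sort_index()
    is_scaffold = counts.index.str.lower().str.startswith(scaffold_prefix)
    return counts[~is_scaffold], counts[is_scaffold]


def protein_properties(peptide: str) -> tuple[int, float, float]:
    """Length (aa), average molecular weight (Da) and isoelectric point.

    ``X`` (unknown residue) counts toward length but is excluded from the
    mass and charge calculations.  pI is solved by bisection on the
    Henderson–Hasselbalch net charge using the fixed pKa table above.
    """
    if not peptide:
        raise ValueError("empty peptide")
    peptide = peptide.upper()
    known = [aa for aa in peptide if aa in RESIDUE_MASS]
    bad = set(peptide) - set(RESIDUE_MASS) - {"X"}
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    mw = sum(RESIDUE_MASS[aa] for aa in known) + WATER_MASS
    return len(peptide), mw, isoelectric_point(peptide)


def net_charge(peptide: str, ph: float) -> float:
    """Net charge of the peptide at the given pH (EMBOSS pKa set)."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa in peptide.upper():
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-4,
                      max_iter: int = 100) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = net_charge(peptide, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def exon_profile(gene: GeneModel) -> tuple[int, int, bool]:
    """(exon count, intron count, UTR presence) for one transcript.

    UTR presence is inferred from the annotation: the exon span extends
    beyond the CDS span (or no CDS features are annotated at all).
    """
    n_exons = gene.n_exons
    n_introns = max(n_exons - 1, 0)
    if not gene.exons:
        return 0, 0, False
    if not gene.cds_spans:
        return n_exons, n_introns, True
    exon_lo, exon_hi = gene.exons[0][0], gene.exons[-1][1]
    cds_lo, cds_hi = gene.cds_spans[0][0], gene.cds_spans[-1][1]
    has_utr = exon_lo < cds_lo or exon_hi > cds_hi
    return n_exons, n_introns, has_utr


def read_catalog(path: str) -> pd.DataFrame:
    """Read a catalog TSV written by :meth:`FamilyCatalog.to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return df.set_index("gene_id")
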