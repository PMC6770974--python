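"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap
supports, and reference-anchored clade classification.

The neighbor-joining agglomeration (Saitou & Nei) is exact on additive
distance matrices: the path-length matrix of the returned tree reproduces
the input exactly.  All tie-breaks are lexicographic on taxon labels so a
given matrix always yields the same tree.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

GAP = "-"
_TIE_EPS = 1e-12


@dataclass
class Alignment:
    """A gapped amino-acid alignment (rows of equal length)."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and rows differ in number")
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least two taxa")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        return np.array([np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                         for s in self.seqs])


def read_alignment(path: str) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    return Alignment([r.id for r in records],
                     [str(r.seq).upper() for r in records])


def p_distance(
    aln: Alignment,
    site_policy: str = "complete_deletion",
    correction: str | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pairwise proportion-of-mismatches distances.

    ``complete_deletion`` uses only columns free of gaps in every row
    ("conserved sites"); ``pairwise_deletion`` uses, per pair, the columns
    where both rows are ungapped.  ``correction="poisson"`` applies
    d = -ln(1 - p) for multiple amino-acid hits.
    """
    if site_policy not in ("complete_deletion", "pairwise_deletion"):
        raise ValueError(f"unknown site policy {site_policy!r}")
    mat = aln.matrix()
    gap = ord(GAP)
    if site_policy == "complete_deletion":
        keep = (mat != gap).all(axis=0)
        sub = mat[:, keep]
        if sub.shape[1] == 0:
            raise ValueError("no gap-free columns shared by all taxa")
        diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=-1)
        D = diff / sub.shape[1]
    else:
        ungapped = mat != gap
        comparable = ungapped[:, None, :] & ungapped[None, :, :]
        n_comp = comparable.sum(axis=-1)
        off = ~np.eye(len(aln.ids), dtype=bool)
        if (n_comp[off] == 0).any():
            raise ValueError("a taxon pair shares zero comparable sites")
        mism = ((mat[:, None, :] != mat[None, :, :]) & comparable).sum(axis=-1)
        with np.errstate(invalid="ignore"):
            D = mism / np.maximum(n_comp, 1)
    np.fill_diagonal(D, 0.0)
    if correction == "poisson":
        if (D[~np.eye(len(D), dtype=bool)] >= 1.0).any():
            raise ValueError("p = 1 cannot be Poisson-corrected")
        D = -np.log(1.0 - D)
        np.fill_diagonal(D, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return list(aln.ids), D


def _validate_matrix(D: np.ndarray) -> None:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")


def nj_tree(D: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    """Neighbor joining with lexicographic tie-breaking.

    Joins the pair minimizing the Q criterion; among numerically tied pairs
    the one with the lexicographically smallest (sorted) pair of cluster
    labels wins, a cluster's label being its smallest leaf name.  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling branch so the joined pair's path length is preserved.
    """
    D = np.asarray(D, dtype=float).copy()
    _validate_matrix(D)
    n = len(taxa)
    if n != D.shape[0]:
        raise ValueError("taxa/matrix size mismatch")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(taxa)
    nodes: list[dendropy.Node] = []
    for name in taxa:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    labels = list(taxa)          # tie-break label per working node
    active = list(range(n))

    # grow D in place: preallocate for all internal nodes
    full = np.zeros((2 * n, 2 * n))
    full[:n, :n] = D
    D = full
    next_idx = n

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + _TIE_EPS)
        i, j = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda p: tuple(sorted((labels[active[p[0]]],
                                        labels[active[p[1]]]))),
        )
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = li
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = lj
        nodes.append(parent)
        labels.append(min(labels[gi], labels[gj]))
        for k in active:
            if k in (gi, gj):
                continue
            duk = 0.5 * (D[gi, k] + D[gj, k] - dij)
            D[next_idx, k] = D[k, next_idx] = duk
        active = [k for k in active if k not in (gi, gj)] + [next_idx]
        next_idx += 1

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for g, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[g])
        nodes[g].edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree,
                       taxa: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths in the order of ``taxa``."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    out = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                d = pdm.patristic_distance(tns.get_taxon(ti),
                                           tns.get_taxon(tj))
                out[i, j] = out[j, i] = d
    return out


def _resample(aln: Alignment, cols: np.ndarray) -> Alignment:
    mat = aln.matrix()[:, cols]
    return Alignment(list(aln.ids),
                     [bytes(row).decode("ascii") for row in mat])


def _internal_bitmasks(tree: dendropy.Tree) -> list[int]:
    tree.encode_bipartitions()
    masks = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        masks.append(edge.bipartition.split_bitmask)
    return masks


def bootstrap(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int | None = None,
    site_policy: str = "complete_deletion",
    correction: str | None = None,
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports (0-100).

    Columns are resampled with replacement per replicate; an internal
    edge's support is the percentage of replicate trees containing the
    same bipartition.  Deterministic for a fixed seed: the resampling
    depends only on the seed and the number of columns, never on taxon
    order, so supports are invariant under taxon permutation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    taxa, D = p_distance(aln, site_policy, correction)
    main = nj_tree(D, taxa)
    tns = main.taxon_namespace

    rng = np.random.default_rng(seed)
    counts: Counter[int] = Counter()
    n_cols = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = _resample(aln, cols)
        try:
            rep_taxa, rep_D = p_distance(rep_aln, site_policy, correction)
        except ValueError:
            continue  # replicate with no usable columns
        rep_tree = nj_tree(rep_D, rep_taxa)
        rep_tree.migrate_taxon_namespace(tns)
        counts.update(set(_internal_bitmasks(rep_tree)))

    main.encode_bipartitions()
    for edge in main.preorder_edge_iter():
        head = edge.head_node
        if head is main.seed_node or head.is_leaf():
            continue
        support = 100.0 * counts[edge.bipartition.split_bitmask] / n_reps
        head.label = str(int(round(support)))
    return main


def assign_classes(
    tree: dendropy.Tree,
    reference_labels: dict[str, str],
) -> dict[str, str]:
    """Label each non-reference leaf by its nearest pure reference clade.

    The tree is midpoint-rooted (on the longest leaf-to-leaf path); each
    unlabeled leaf takes class C iff the smallest clade containing the
    leaf and at least one reference holds references of class C only,
    otherwise it is "unresolved".
    """
    if not reference_labels:
        raise ValueError("no reference labels given")
    work = tree.clone(depth=1)
    leaf_names = {lf.taxon.label for lf in work.leaf_node_iter()}
    present = set(reference_labels) & leaf_names
    if not present:
        raise ValueError("no reference taxa present in the tree")
    work.reroot_at_midpoint(update_bipartitions=False)

    result: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference_labels:
            continue
        node = leaf.parent_node
        assigned = "unresolved"
        while node is not None:
            refs = {reference_labels[lf.taxon.label]
                    for lf in node.leaf_iter()
                    if lf.taxon.label in reference_labels}
            if refs:
                assigned = refs.pop() if len(refs) == 1 else "unresolved"
                break
            node = node.parent_node
        result[name] = assigned
    return result


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick",
                             preserve_underscores=True)


def read_reference_labels(path: str) -> dict[str, str]:
    """Read a two-column TSV mapping taxon -> class."""
    labels = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, _, cls = line.partition("\t")
            if taxon == "taxon" and cls == "class":
                continue  # header
            labels[taxon] = cls
    return labels


def write_class_map(classes: dict[str, str], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("taxon\tclass\n")
        for taxon in sorted(classes):
            handle.write(f"{taxon}\t{classes[taxon]}\n")
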