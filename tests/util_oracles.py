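"""Brute-force oracles used by the duplication and selection tests.

Written directly from the definitions (codon pathway enumeration, longest
monotone chain by exhaustive search, average pairwise differences); no
code is shared with the implementations under test.
"""

import itertools
from functools import lru_cache

GENETIC_CODE = {}
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
          "VVVVAAAADDEEGGGG")
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_a + _b + _c] = _AMINO[_i]

STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count; mutations to stops count as nonsynonymous."""
    total = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt not in STOPS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                total += 1 / 3
    return total


@lru_cache(maxsize=None)
def oracle_pathways(ca: str, cb: str) -> tuple[float, float]:
    """Mean (syn, nonsyn) steps over stop-free minimal pathways."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        steps = []
        cur = ca
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for blocked, s in paths if not blocked]
    if not usable:
        usable = [s for _, s in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE.get(cur, "*") \
                    and nxt not in STOPS and cur not in STOPS:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(usable), nonsyn / len(usable)


def oracle_longest_chain(anchors, max_gap: int, inverted: bool) -> int:
    """Length of the longest valid chain, by exhaustive extension.

    ``anchors`` is a list of (rank_a, rank_b) pairs; a valid chain is
    strictly increasing in rank_a, strictly monotone in rank_b (direction
    set by ``inverted``), with consecutive gaps <= max_gap in both.
    """
    order = sorted(range(len(anchors)), key=lambda i: anchors[i])

    def extend(last_idx: int) -> int:
        ra, rb = anchors[last_idx]
        best = 0
        for j in order:
            qa, qb = anchors[j]
            da = qa - ra
            db = (qb - rb) if not inverted else (rb - qb)
            if 0 < da <= max_gap and 0 < db <= max_gap:
                best = max(best, extend(j))
        return 1 + best

    return max((extend(i) for i in order), default=0)


def oracle_pairwise_pi(genotypes, positions, window) -> float:
    """Average pairwise differences per bp over allele copies.

    ``genotypes``: (n_sites, n_samples, 2) with -1 for missing; per site
    every pair of called allele copies is compared; the per-site mean
    pairwise difference is summed over sites in the half-open window and
    divided by the window span.
    """
    start, end = window
    total = 0.0
    for s, pos in enumerate(positions):
        if not (start <= pos - 1 < end):
            continue
        alleles = [a for pair in genotypes[s] for a in pair if a >= 0]
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(1 for i in range(n) for j in range(i + 1, n)
                   if alleles[i] != alleles[j])
        total += diff / (n * (n - 1) / 2)
    return total / (end - start)
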