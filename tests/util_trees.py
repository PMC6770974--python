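"""Independent additive-tree oracle used by the phylogeny tests.

Builds random unrooted binary trees by leaf insertion, keeps an explicit
edge list, and computes leaf-to-leaf path lengths by graph traversal —
no code shared with the neighbor-joining implementation under test.
"""

from collections import defaultdict

import numpy as np


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths in [0.1, 1.1].

    Returns (taxa, edges) where edges is a dict {(u, v): length} over
    node ids; leaves are ids 0..n_taxa-1.
    """
    assert n_taxa >= 3
    next_node = n_taxa
    center = next_node
    next_node += 1
    edges = {}
    for leaf in range(3):
        edges[(center, leaf)] = rng.uniform(0.1, 1.1)
    for leaf in range(3, n_taxa):
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = rng.uniform(0.25, 0.75) * length
        edges[(u, mid)] = split
        edges[(mid, v)] = length - split
        edges[(mid, leaf)] = rng.uniform(0.1, 1.1)
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    return taxa, edges


def path_lengths(n_taxa: int, edges: dict) -> np.ndarray:
    adj = defaultdict(list)
    for (u, v), ln in edges.items():
        adj[u].append((v, ln))
        adj[v].append((u, ln))
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, ln in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + ln
                    stack.append(nxt)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    return D


def tree_splits(n_taxa: int, edges: dict) -> set[frozenset]:
    """Non-trivial bipartitions as leaf-id sets on the side without leaf 0."""
    adj = defaultdict(list)
    for (u, v), _ in edges.items():
        adj[u].append(v)
        adj[v].append(u)
    splits = set()
    for (u, v) in edges:
        # leaves reachable from v without crossing the (u, v) edge
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node < n_taxa:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 0 in side:
            side = set(range(n_taxa)) - side
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(frozenset(side))
    return splits


def dendropy_splits(tree, taxa: list[str]) -> set[frozenset]:
    """The same normalized splits, read off a dendropy tree."""
    index = {name: i for i, name in enumerate(taxa)}
    n = len(taxa)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {index[lf.taxon.label] for lf in node.leaf_iter()}
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits
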