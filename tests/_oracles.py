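"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: distances via explicit
root-path edge sets, the pairwise test via exhaustive search over
edge-disjoint pair subsets, subset selection via full enumeration.
"""

from itertools import combinations

import numpy as np


def path_edges(tree):
    """tip label -> frozenset of edge ids on its root path."""
    out = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(id(node.edge))
            node = node.parent_node
        out[leaf.taxon.label] = frozenset(edges)
    return out


def edge_lengths(tree):
    return {id(e): (e.length or 0.0) for e in tree.preorder_edge_iter()}


def brute_patristic(tree, a: str, b: str) -> float:
    """Path length via symmetric difference of root-path edge sets."""
    paths = path_edges(tree)
    lengths = edge_lengths(tree)
    return sum(lengths[e] for e in paths[a] ^ paths[b])


def brute_max_contrasting_pairs(tree, genotype: dict, phenotype: dict):
    """Exhaustive search over edge-disjoint contrasting-pair subsets.

    Returns (max_pairs, worst_supporting, best_supporting).
    """
    paths = path_edges(tree)
    tips = list(paths)
    candidates = []  # (edge set of the pair path, supporting flag)
    for a, b in combinations(tips, 2):
        if genotype[a] == genotype[b] or phenotype[a] == phenotype[b]:
            continue
        pos = a if genotype[a] == 1 else b
        supporting = phenotype[pos] == 1
        candidates.append((paths[a] ^ paths[b], supporting))

    best_count = 0
    supports_at_best: set[int] = {0}

    def search(idx, used, count, support):
        nonlocal best_count, supports_at_best
        if count > best_count:
            best_count = count
            supports_at_best = {support}
        elif count == best_count:
            supports_at_best.add(support)
        for k in range(idx, len(candidates)):
            edges, sup = candidates[k]
            if used & edges:
                continue
            search(k + 1, used | edges, count + 1, support + int(sup))

    search(0, frozenset(), 0, 0)
    return best_count, min(supports_at_best), max(supports_at_best)


def brute_matched_subsets(D, pma_ids, npma_ids, size):
    """All subsets of the pool with their focal-to-subset mean distances."""
    block = D.loc[list(pma_ids), list(npma_ids)]
    out = {}
    for subset in combinations(npma_ids, size):
        out[frozenset(subset)] = float(block.loc[:, list(subset)].to_numpy().mean())
    return out


def brute_pan_core(counts: np.ndarray, cols) -> tuple[int, int]:
    """Pan/core sizes of a genome column subset by direct counting."""
    sub = counts[:, list(cols)] >= 1
    return int(sub.any(axis=1).sum()), int(sub.all(axis=1).sum())
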