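"""Independent least-squares tree oracle for tests.

Everything here is written from scratch against the plain definition of the
unweighted least-squares distance-tree problem: enumerate every unrooted
binary topology by sequential leaf addition, solve each for branch lengths
with an ordinary lstsq on the path-incidence system, and return the
topology with the smallest residual.  It deliberately shares no code with
the package's fitting routines.
"""

from itertools import combinations

import numpy as np

# Topologies are edge lists over nodes where leaves are 0..n-1 and internal
# nodes are numbered upward from n.


def enumerate_topologies(n_leaves):
    """Yield every unrooted binary topology over n_leaves labelled leaves."""
    assert n_leaves >= 3
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]

    def grow(edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield list(edges)
            return
        for k in range(len(edges)):
            u, v = edges[k]
            expanded = (
                edges[:k]
                + edges[k + 1 :]
                + [(u, next_internal), (next_internal, v), (next_internal, next_leaf)]
            )
            yield from grow(expanded, next_leaf + 1, next_internal + 1)

    yield from grow(base, 3, n_leaves + 1)


def _paths(n_leaves, edges):
    adjacency = {}
    for index, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, index))
        adjacency.setdefault(v, []).append((u, index))
    incidence = []
    for i, j in combinations(range(n_leaves), 2):
        # depth-first walk from i to j, remembering the edge trail
        stack = [(i, None, [])]
        seen = {i}
        trail = None
        while stack:
            node, _, path = stack.pop()
            if node == j:
                trail = path
                break
            for neighbor, index in adjacency[node]:
                if neighbor not in seen:
                    seen.add(neighbor)
                    stack.append((neighbor, node, path + [index]))
        row = np.zeros(len(edges))
        row[trail] = 1.0
        incidence.append(row)
    return np.array(incidence)


def ls_fit(n_leaves, edges, dvec):
    """Ordinary least-squares branch lengths (clamped at 0) and residual."""
    incidence = _paths(n_leaves, edges)
    lengths, *_ = np.linalg.lstsq(incidence, dvec, rcond=None)
    lengths = np.maximum(lengths, 0.0)
    residual = float(np.sum((incidence @ lengths - dvec) ** 2))
    return lengths, residual


def best_tree(dvec, n_leaves):
    """Exhaustive minimum of the LS residual over all topologies."""
    best = None
    for edges in enumerate_topologies(n_leaves):
        lengths, residual = ls_fit(n_leaves, edges, dvec)
        if best is None or residual < best[2]:
            best = (edges, lengths, residual)
    return best


def bipartitions(n_leaves, edges):
    """Canonical nontrivial leaf splits (side not containing leaf 0)."""
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            for neighbor in adjacency[node]:
                if neighbor in seen:
                    continue
                seen.add(neighbor)
                if neighbor < n_leaves:
                    side.add(neighbor)
                else:
                    stack.append(neighbor)
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(frozenset(side))
    return splits


def random_additive_matrix(rng, n_leaves, low=0.02, high=0.12):
    """A distance matrix realized exactly by a random binary tree.

    Returns (matrix, generating edge list, generating lengths).
    """
    all_topologies = list(enumerate_topologies(n_leaves))
    edges = all_topologies[rng.integers(len(all_topologies))]
    lengths = rng.uniform(low, high, size=len(edges))
    incidence = _paths(n_leaves, edges)
    dvec = incidence @ lengths
    matrix = np.zeros((n_leaves, n_leaves))
    for (i, j), value in zip(combinations(range(n_leaves), 2), dvec):
        matrix[i, j] = matrix[j, i] = value
    return matrix, edges, lengths
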