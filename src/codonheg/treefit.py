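"""Least-squares distance trees over strain codon-usage profiles.

The topology is obtained by neighbor joining, branch lengths are then
re-estimated by unweighted least squares (the Fitch–Margoliash objective
with power 0: minimize the sum of squared differences between tree path
lengths and the input distances), and nearest-neighbor-interchange moves
are accepted while the residual decreases.  The procedure is deterministic
given the input order.  Negative least-squares branch-length estimates are
clamped to zero after fitting, and the residual is reported for the clamped
lengths.

Trees are stored as explicit edge lists: leaves are nodes ``0..n-1`` in
label order, internal nodes are ``>= n``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import squareform

from .compare import DistanceMatrix
from .genome_io import PathLike

log = logging.getLogger(__name__)

Edge = Tuple[int, int]


def _adjacency(edges: Sequence[Edge]) -> Dict[int, List[Tuple[int, int]]]:
    adj: Dict[int, List[Tuple[int, int]]] = defaultdict(list)
    for index, (u, v) in enumerate(edges):
        adj[u].append((v, index))
        adj[v].append((u, index))
    return adj


def _pair_incidence(n_leaves: int, edges: Sequence[Edge]) -> np.ndarray:
    """0/1 matrix: rows are leaf pairs (i<j, lexicographic), cols are edges."""
    adj = _adjacency(edges)
    rows = []
    for i in range(n_leaves):
        parent: Dict[int, Tuple[Optional[int], Optional[int]]] = {i: (None, None)}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, edge_index in adj[u]:
                if v not in parent:
                    parent[v] = (u, edge_index)
                    stack.append(v)
        for j in range(i + 1, n_leaves):
            row = np.zeros(len(edges))
            node = j
            while node != i:
                prev, edge_index = parent[node]
                row[edge_index] = 1.0
                node = prev  # type: ignore[assignment]
            rows.append(row)
    return np.asarray(rows)


def _ls_fit(
    n_leaves: int, edges: Sequence[Edge], dvec: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Unweighted least-squares branch lengths; negatives clamped to zero."""
    incidence = _pair_incidence(n_leaves, edges)
    lengths, *_ = np.linalg.lstsq(incidence, dvec, rcond=None)
    negative = lengths < 0
    if negative.any():
        log.debug("clamping %d negative branch-length estimates", negative.sum())
        lengths = np.maximum(lengths, 0.0)
    residual = float(np.sum((incidence @ lengths - dvec) ** 2))
    return lengths, residual


def _suppress_degree_two(edges: List[Edge], n_leaves: int) -> List[Edge]:
    while True:
        adj = _adjacency(edges)
        target = next(
            (
                node
                for node, neighbors in adj.items()
                if node >= n_leaves and len(neighbors) == 2
            ),
            None,
        )
        if target is None:
            return edges
        (a, _), (b, _) = adj[target]
        edges = [e for e in edges if target not in e] + [(a, b)]


def _nj_topology(d: np.ndarray) -> List[Edge]:
    """Neighbor-joining topology as an edge list (branch lengths discarded)."""
    n = d.shape[0]
    if n == 3:
        return [(0, 3), (1, 3), (2, 3)]
    from skbio import DistanceMatrix as _SkbioDM  # deferred: heavy import
    from skbio.tree import nj as _skbio_nj

    ids = [f"t{i}" for i in range(n)]
    tree = _skbio_nj(_SkbioDM(d, ids))
    node_ids: Dict[int, int] = {}
    next_internal = n
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            node_ids[id(node)] = int(node.name[1:])
        else:
            node_ids[id(node)] = next_internal
            next_internal += 1
    edges = [
        (node_ids[id(node.parent)], node_ids[id(node)])
        for node in tree.traverse(include_self=False)
    ]
    return _suppress_degree_two(edges, n)


def _internal_edges(edges: Sequence[Edge], n_leaves: int) -> List[Edge]:
    return [(u, v) for u, v in edges if u >= n_leaves and v >= n_leaves]


def _swap_subtrees(edges: Sequence[Edge], u: int, x: int, v: int, y: int) -> List[Edge]:
    """Detach subtree x from u and subtree y from v, and swap them."""
    swapped = []
    for a, b in edges:
        pair = {a, b}
        if pair == {u, x}:
            swapped.append((u, y))
        elif pair == {v, y}:
            swapped.append((v, x))
        else:
            swapped.append((a, b))
    return swapped


def _nni_variants(edges: Sequence[Edge], n_leaves: int) -> List[List[Edge]]:
    """The two nearest-neighbor-interchange rearrangements per internal edge."""
    adj = _adjacency(edges)
    variants = []
    for u, v in _internal_edges(edges, n_leaves):
        u_neighbors = [w for w, _ in adj[u] if w != v]
        v_neighbors = [w for w, _ in adj[v] if w != u]
        moved = u_neighbors[1]
        for other in v_neighbors:
            variants.append(_swap_subtrees(edges, u, moved, v, other))
    return variants


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class PhyloTree:
    """An unrooted tree over strain labels with least-squares branch lengths.

    Leaves are nodes ``0..n-1`` (in ``labels`` order), internal nodes are
    larger integers.  ``residual`` is the unweighted least-squares mismatch
    between tree path lengths and the fitted distance matrix.
    """

    labels: Tuple[str, ...]
    edges: Tuple[Edge, ...]
    lengths: np.ndarray
    residual: float

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def path_length_matrix(self) -> np.ndarray:
        """Pairwise leaf-to-leaf path lengths, in label order."""
        incidence = _pair_incidence(self.n_leaves, self.edges)
        return squareform(incidence @ self.lengths)

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial label splits induced by internal edges.

        Each split is represented by the side not containing the first
        label, so representations are canonical and comparable across trees.
        """
        adj = _adjacency(self.edges)
        n = self.n_leaves
        splits: Set[FrozenSet[str]] = set()
        for u, v in _internal_edges(self.edges, n):
            # leaves reachable from v without crossing (u, v)
            seen = {u, v}
            stack = [v]
            side = []
            while stack:
                node = stack.pop()
                for neighbor, _ in adj[node]:
                    if neighbor in seen:
                        continue
                    seen.add(neighbor)
                    if neighbor < n:
                        side.append(neighbor)
                    else:
                        stack.append(neighbor)
            if 0 in side:
                side = [leaf for leaf in range(n) if leaf not in side]
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset(self.labels[leaf] for leaf in side))
        return splits

    def newick(self) -> str:
        """Serialize as Newick with branch lengths to 6 decimals.

        The unrooted tree is written rooted at the internal node adjacent to
        the first leaf; children are ordered by their smallest descendant
        leaf, so output is deterministic.
        """
        adj = _adjacency(self.edges)
        n = self.n_leaves
        if n == 2:
            total = float(self.lengths.sum())
            return (
                f"({_quote_label(self.labels[0])}:{total / 2:.6f},"
                f"{_quote_label(self.labels[1])}:{total / 2:.6f});"
            )
        root = next(v for v, _ in adj[0] if v >= n)

        def min_leaf(node: int, banned_edge: int) -> int:
            best = node if node < n else self.n_leaves + len(self.edges)
            for neighbor, edge_index in adj[node]:
                if edge_index != banned_edge:
                    best = min(best, min_leaf(neighbor, edge_index))
            return best

        def render(node: int, incoming: int) -> str:
            children = [
                (min_leaf(neighbor, edge_index), neighbor, edge_index)
                for neighbor, edge_index in adj[node]
                if edge_index != incoming
            ]
            if not children:  # leaf
                return _quote_label(self.labels[node])
            children.sort()
            parts = [
                f"{render(neighbor, edge_index)}:{self.lengths[edge_index]:.6f}"
                for _, neighbor, edge_index in children
            ]
            return "(" + ",".join(parts) + ")"

        return render(root, -1) + ";"


def fit_tree(matrix: DistanceMatrix, *, nni: bool = True) -> PhyloTree:
    """Fit a least-squares distance tree to a strain distance matrix.

    Neighbor joining provides the starting topology; unweighted least
    squares re-estimates branch lengths on it; nearest-neighbor interchanges
    are applied greedily while the residual decreases (``nni=False`` skips
    the search).  Requires at least 3 taxa and finite distances.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError(f"fit_tree: need at least 3 taxa, got {n}")
    if not np.isfinite(matrix.d).all():
        raise ValueError("fit_tree: distance matrix contains non-finite entries")
    dvec = squareform(matrix.d, checks=False)
    edges = _nj_topology(matrix.d)
    lengths, residual = _ls_fit(n, edges, dvec)
    if nni:
        improved = True
        while improved:
            improved = False
            for candidate in _nni_variants(edges, n):
                cand_lengths, cand_residual = _ls_fit(n, candidate, dvec)
                if cand_residual < residual - 1e-12:
                    edges, lengths, residual = candidate, cand_lengths, cand_residual
                    improved = True
                    break
    clamped = int(np.sum(lengths == 0.0))
    if clamped:
        log.debug("fit_tree: %d branch lengths at the zero bound", clamped)
    return PhyloTree(
        labels=tuple(matrix.labels),
        edges=tuple(edges),
        lengths=lengths,
        residual=residual,
    )


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    """Write the tree as a standard Newick file with a trailing newline."""
    Path(path).write_text(tree.newick() + "\n")
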