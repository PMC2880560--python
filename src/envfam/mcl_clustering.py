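"""Markov Cluster algorithm over the similarity graph.

The graph's raw alignment scores are used directly as edge weights.  The
column-stochastic flow matrix is built with per-node self-loops equal to the
node's maximum incident edge weight (a standard regularisation that makes the
iteration converge), then alternately expanded (matrix square) and inflated
(elementwise power followed by column renormalisation) until the matrix stops
changing.  Clusters are read off the connected structure of the converged
flow.  Node ordering is lexicographic by id so the floating-point iteration is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .similarity import SimilarityEdge


@dataclass
class Partition:
    """Disjoint clusters covering all nodes; size-1 clusters listed separately."""

    clusters: list[frozenset[str]]
    converged: bool = True
    n_iterations: int = 0

    @property
    def singleton_ids(self) -> list[str]:
        return sorted(x for c in self.clusters if len(c) == 1 for x in c)

    @property
    def non_singletons(self) -> list[frozenset[str]]:
        return [c for c in self.clusters if len(c) > 1]


def _adjacency(
    edges: Iterable[SimilarityEdge | tuple],
    nodes: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    triples = []
    seen: set[str] = set(nodes or [])
    for e in edges:
        if isinstance(e, SimilarityEdge):
            a, b, w = e.a, e.b, e.score
        else:
            a, b, w = e[0], e[1], float(e[2])
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        triples.append((a, b, w))
        seen.add(a)
        seen.add(b)
    order = sorted(seen)
    index = {n: i for i, n in enumerate(order)}
    matrix = np.zeros((len(order), len(order)))
    for a, b, w in triples:
        i, j = index[a], index[b]
        if i == j:
            continue
        matrix[i, j] = max(matrix[i, j], w)
        matrix[j, i] = matrix[i, j]
    return order, matrix


def mcl(
    edges: Iterable[SimilarityEdge | tuple],
    nodes: Sequence[str] | None = None,
    inflation: float = 2.0,
    prune_floor: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> Partition:
    """Cluster a weighted undirected graph by Markov clustering.

    ``edges`` may be :class:`SimilarityEdge` objects or (a, b, weight)
    tuples; ``nodes`` can add isolated nodes with no edges.  Non-convergence
    within ``max_iter`` flags the result rather than failing.
    """
    order, adjacency = _adjacency(edges, nodes)
    n = len(order)
    if n == 0:
        return Partition(clusters=[], converged=True, n_iterations=0)

    matrix = adjacency.copy()
    # self-loop per node: maximum incident edge weight (1.0 for isolated nodes)
    loops = matrix.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(matrix, loops)
    matrix /= matrix.sum(axis=0, keepdims=True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        previous = matrix
        matrix = matrix @ matrix  # expansion
        matrix = matrix**inflation  # inflation
        matrix[matrix < prune_floor] = 0.0
        sums = matrix.sum(axis=0, keepdims=True)
        # a column fully pruned away keeps its heaviest entry
        dead = np.flatnonzero(sums[0] == 0.0)
        for j in dead:
            matrix[np.argmax(previous[:, j]), j] = 1.0
        sums = matrix.sum(axis=0, keepdims=True)
        matrix /= sums
        if np.max(np.abs(matrix - previous)) < tol:
            converged = True
            break

    support = (matrix + matrix.T) > 0
    n_comp, assignment = connected_components(support, directed=False)
    clusters: list[frozenset[str]] = []
    for c in range(n_comp):
        members = frozenset(order[i] for i in np.flatnonzero(assignment == c))
        clusters.append(members)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return Partition(clusters=clusters, converged=converged, n_iterations=iterations)


def cluster_size_histogram(partition: Partition, min_size: int = 10) -> pd.DataFrame:
    """Counts of clusters per size, with sub-threshold sizes flagged as
    microfamilies (too small for family-level analysis)."""
    sizes = pd.Series([len(c) for c in partition.clusters], dtype=int)
    if sizes.empty:
        return pd.DataFrame(columns=["size", "n_clusters", "microfamily"])
    hist = sizes.value_counts().sort_index()
    return pd.DataFrame(
        {
            "size": hist.index,
            "n_clusters": hist.values,
            "microfamily": hist.index < min_size,
        }
    ).reset_index(drop=True)


def write_clusters(partition: Partition, path) -> None:
    """One cluster per line, tab-separated ids, size-descending then by id."""
    with open(path, "w") as handle:
        for cluster in partition.clusters:
            handle.write("\t".join(sorted(cluster)) + "\n")
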