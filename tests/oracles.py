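"""Independent reference implementations used only to cross-check envfam.

These are deliberately written from first principles, in a different style
and along different recurrences than the package code, so a defect in the
implementation cannot be replicated here.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sub_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def enumerate_local_score(x: str, y: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Brute-force enumeration over every set of aligned residue pairs.

    A local alignment is a set of index pairs, strictly increasing in both
    sequences; unpaired residues between consecutive pairs form gap runs, a
    run of length L costing gap_open + L * gap_extend.  Feasible only for
    very short sequences.
    """
    n, m = len(x), len(y)
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for xi in itertools.combinations(range(n), k):
            for yi in itertools.combinations(range(m), k):
                score = sum(sub_score(x[i], y[j]) for i, j in zip(xi, yi))
                for t in range(1, k):
                    dx = xi[t] - xi[t - 1] - 1
                    dy = yi[t] - yi[t - 1] - 1
                    if dx:
                        score -= gap_open + dx * gap_extend
                    if dy:
                        score -= gap_open + dy * gap_extend
                best = max(best, score)
    return best


def recursive_local_score(x: str, y: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Top-down memoized recursion for the optimal local affine-gap score."""
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def diag(i: int, j: int) -> float:
        # best alignment ending with x[i-1] paired to y[j-1]
        if i == 0 or j == 0:
            return -1e30
        prev = max(0.0, diag(i - 1, j - 1), gx(i - 1, j - 1), gy(i - 1, j - 1))
        return prev + sub_score(x[i - 1], y[j - 1])

    @lru_cache(maxsize=None)
    def gx(i: int, j: int) -> float:
        # best alignment ending with a gap run consuming x up to i
        if i == 0:
            return -1e30
        return max(diag(i - 1, j) - first, gx(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def gy(i: int, j: int) -> float:
        if j == 0:
            return -1e30
        return max(diag(i, j - 1) - first, gy(i, j - 1) - gap_extend)

    best = 0.0
    for i in range(1, len(x) + 1):
        for j in range(1, len(y) + 1):
            best = max(best, diag(i, j))
    return best


def mcl_oracle(
    edges,
    nodes=(),
    inflation: float = 2.0,
    prune_floor: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[frozenset[str]]:
    """Plain, loop-level Markov clustering used to validate the package's
    implementation: same definition, separately coded."""
    names = set(nodes)
    weights = {}
    for a, b, w in edges:
        names.add(a)
        names.add(b)
        if a != b:
            key = (min(a, b), max(a, b))
            weights[key] = max(weights.get(key, 0.0), float(w))
    order = sorted(names)
    pos = {n: i for i, n in enumerate(order)}
    size = len(order)
    M = [[0.0] * size for _ in range(size)]
    for (a, b), w in weights.items():
        M[pos[a]][pos[b]] = w
        M[pos[b]][pos[a]] = w
    for j in range(size):
        incident = max(M[i][j] for i in range(size)) if size else 0.0
        M[j][j] = incident if incident > 0 else 1.0
    for j in range(size):
        total = sum(M[i][j] for i in range(size))
        for i in range(size):
            M[i][j] /= total

    M = np.array(M)
    for _ in range(max_iter):
        prev = M
        M = prev @ prev
        M = np.power(M, inflation)
        M = np.where(M < prune_floor, 0.0, M)
        for j in range(size):
            colsum = M[:, j].sum()
            if colsum == 0.0:
                M[int(np.argmax(prev[:, j])), j] = 1.0
                colsum = 1.0
            M[:, j] = M[:, j] / colsum
        if np.abs(M - prev).max() < tol:
            break

    # clusters: connected components of the nonzero support (symmetrized)
    adjacency = {n: set() for n in order}
    for i in range(size):
        for j in range(size):
            if M[i][j] > 0.0:
                adjacency[order[i]].add(order[j])
                adjacency[order[j]].add(order[i])
    seen: set[str] = set()
    clusters = []
    for start in order:
        if start in seen:
            continue
        stack, component = [start], set()
        while stack:
            node = stack.pop()
            if node in component:
                continue
            component.add(node)
            stack.extend(adjacency[node] - component)
        seen |= component
        clusters.append(frozenset(component))
    return sorted(clusters, key=lambda c: (-len(c), min(c)))
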