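"""Pairwise local alignment, the score-threshold similarity graph, and greedy
identity reduction of a sequence database.

The pairwise engine is Smith–Waterman with affine gaps (BLOSUM62, gap open 11,
gap extend 1 by default).  A gap run of length L costs ``gap_open +
L * gap_extend``.  The raw alignment score plays the role of the classic
"score >= 60" homology criterion used to draw edges of the clustering graph;
raw score is used (not a bit score) so edges do not depend on database size.
Identity is counted as matches / alignment columns, gap columns included.

``'X'`` (masked residues) scores 0 against everything, so masked segments can
neither create nor destroy similarity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidResidueError
from .sequence_io import Interval, ProteinRecord, VALID_RESIDUES


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap penalties for pairwise alignment."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def substitution_matrix(self) -> substitution_matrices.Array:
        return _masked_matrix(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.substitution_matrix()
        # first gapped position costs open+extend, later ones extend each:
        # a run of length L costs gap_open + L * gap_extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@lru_cache(maxsize=None)
def _masked_matrix(name: str) -> substitution_matrices.Array:
    matrix = substitution_matrices.load(name).copy()
    # masked residues are neutral: zero against everything
    if "X" in matrix.alphabet:
        for letter in matrix.alphabet:
            matrix["X", letter] = 0.0
            matrix[letter, "X"] = 0.0
    return matrix


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float
    span_a: tuple[int, int]  # half-open on the first sequence
    span_b: tuple[int, int]


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    score: float
    identity: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]


def _check_residues(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise InvalidResidueError(f"{name} contains invalid residues {sorted(bad)}")


_EMPTY = AlignmentResult(0.0, 0.0, (0, 0), (0, 0))


def local_align(
    x: str, y: str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal local alignment of two sequences.

    Returns the raw score, fractional identity (matches over alignment
    columns, counting gap columns) and the aligned spans on both sequences.
    A pair with no positive-scoring alignment returns score 0.
    """
    scheme = scheme or ScoringScheme()
    _check_residues(x, "x")
    _check_residues(y, "y")
    aligner = scheme.aligner()
    score = aligner.score(x, y)
    if score <= 0:
        return _EMPTY
    alignment = next(iter(aligner.align(x, y)))
    counts = alignment.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    columns = gaps + identities + mismatches
    blocks_x, blocks_y = alignment.aligned
    span_a = (int(blocks_x[0][0]), int(blocks_x[-1][1]))
    span_b = (int(blocks_y[0][0]), int(blocks_y[-1][1]))
    return AlignmentResult(
        score=float(score),
        identity=identities / columns if columns else 0.0,
        span_a=span_a,
        span_b=span_b,
    )


def alignment_score(x: str, y: str, scheme: ScoringScheme | None = None) -> float:
    """Score-only fast path (no traceback)."""
    scheme = scheme or ScoringScheme()
    return float(scheme.aligner().score(x, y))


# ---------------------------------------------------------------------------
# k-mer prefilter
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1) if "X" not in seq[i : i + k])


def _shared_kmers(a: frozenset[str], b: frozenset[str]) -> int:
    if len(a) > len(b):
        a, b = b, a
    return sum(1 for kmer in a if kmer in b)


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def build_graph(
    records: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    min_score: float = 60.0,
    prefilter: bool = True,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
) -> list[SimilarityEdge]:
    """All-vs-all comparison; keep undirected edges with score >= min_score.

    The optional shared-k-mer prefilter skips pairs sharing fewer than
    ``prefilter_min_shared`` distinct k-mers; it is a heuristic speed-up and
    can be disabled for exhaustive comparison.
    """
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    seqs = [r.sequence for r in records]
    kmer_sets = [_kmers(s, prefilter_k) for s in seqs] if prefilter else None
    edges: list[SimilarityEdge] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if kmer_sets is not None and _shared_kmers(
                kmer_sets[i], kmer_sets[j]
            ) < prefilter_min_shared:
                continue
            score = aligner.score(seqs[i], seqs[j])
            if score < min_score:
                continue
            result = local_align(seqs[i], seqs[j], scheme)
            edges.append(
                SimilarityEdge(
                    a=records[i].id,
                    b=records[j].id,
                    score=result.score,
                    identity=result.identity,
                    span_a=result.span_a,
                    span_b=result.span_b,
                )
            )
    return edges


def write_edges(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["a", "b", "score", "identity"])
        for e in edges:
            writer.writerow([e.a, e.b, f"{e.score:g}", f"{e.identity:.4f}"])


# ---------------------------------------------------------------------------
# Greedy identity reduction (non-redundant database construction)
# ---------------------------------------------------------------------------

def reduce_identity(
    records: Sequence[ProteinRecord],
    threshold: float = 0.85,
    min_coverage: float = 0.8,
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
    prefilter_k: int = 8,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy longest-first clustering at a fractional-identity threshold.

    Each sequence joins the first (longest-first, ties by id) representative
    it aligns to with identity >= *threshold* over >= *min_coverage* of the
    shorter sequence; otherwise it becomes a new representative.  Returns the
    representatives and a membership map (every input id -> representative id).
    """
    scheme = scheme or ScoringScheme()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[ProteinRecord] = []
    rep_kmers: list[frozenset[str]] = []
    membership: dict[str, str] = {}
    for record in ordered:
        kmers = _kmers(record.sequence, prefilter_k) if prefilter else None
        assigned = False
        for idx, rep in enumerate(representatives):
            if kmers is not None and _shared_kmers(kmers, rep_kmers[idx]) < 1:
                continue
            result = local_align(record.sequence, rep.sequence, scheme)
            shorter = min(len(record.sequence), len(rep.sequence))
            covered = result.span_a[1] - result.span_a[0]
            if result.identity >= threshold and covered >= min_coverage * shorter:
                membership[record.id] = rep.id
                assigned = True
                break
        if not assigned:
            representatives.append(record)
            if prefilter:
                rep_kmers.append(kmers if kmers is not None else _kmers(record.sequence, prefilter_k))
            else:
                rep_kmers.append(frozenset())
            membership[record.id] = record.id
    return representatives, membership
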