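"""Per-position profile models: construction from alignments, significance
calibration, database scanning, iterative enrichment, and overlap-driven
cluster merging.

A profile is a position x residue log-odds matrix in half-bit units,
``2 * log2(p_i(a) / q(a))`` with a Dirichlet pseudocount against a uniform
background ``q(a) = 1/20``.  Scanning is position-specific Smith-Waterman
(local, affine gaps) of the profile against a sequence; masked residues
('X') score 0 at every position.

Significance is empirical: the maximum local score of the profile against
i.i.d. random decoys follows a Gumbel law whose location/scale are fitted per
model; E-values are ``Z * P(score >= S)`` with an effective database size
``Z`` (default 2,000), mirroring classic profile-search ``-Z`` semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .errors import (
    CalibrationError,
    FamilyCollapseError,
    UncalibratedModelError,
)
from .sequence_io import AMINO_ACIDS, Interval, ProteinRecord
from .similarity import ScoringScheme, local_align

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE_TABLE = np.full(128, -1, dtype=np.int8)
for _aa, _i in _AA_INDEX.items():
    _CODE_TABLE[ord(_aa)] = _i

GAP = "-"
_BACKGROUND = 0.05  # uniform q(a) over the 20 residues


def encode(sequence: str) -> np.ndarray:
    """Residues to 0..19 codes; 'X' (and gaps) to -1 (scores 0 everywhere)."""
    return _CODE_TABLE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class ProfileModel:
    model_id: str
    scores: np.ndarray  # (length, 20) half-bit log-odds
    gap_open: float = 11.0
    gap_extend: float = 1.0
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None
    z_constant: float = 2000.0
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    def evalue(self, score: float) -> float:
        """Expected number of false hits at or above *score*."""
        if not self.calibrated:
            raise UncalibratedModelError(
                f"model {self.model_id!r} has no Gumbel calibration"
            )
        x = self.gumbel_lambda * (score - self.gumbel_mu)
        # P(max >= s) under Gumbel; stable in both tails
        if x > 700.0:
            p = math.exp(-x)  # tail approximation, exact to double precision
        else:
            p = -math.expm1(-math.exp(-x))
        return self.z_constant * p

    def score_threshold(self, max_evalue: float) -> float:
        """Smallest score whose E-value is <= max_evalue (tail inversion)."""
        if not self.calibrated:
            raise UncalibratedModelError(
                f"model {self.model_id!r} has no Gumbel calibration"
            )
        p = max_evalue / self.z_constant
        if p >= 1.0:
            return -np.inf
        return self.gumbel_mu - math.log(-math.log1p(-min(p, 1 - 1e-16))) / self.gumbel_lambda


@dataclass(frozen=True)
class ProfileHit:
    model_id: str
    seq_id: str
    score: float
    evalue: float
    span: Interval  # on the sequence
    model_span: tuple[int, int] = (0, 0)
    #: sequence index aligned to each model position in model_span, -1 = gap
    aligned: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Numba DP kernels (local profile-vs-sequence alignment, affine gaps)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_score(scores, code, gap_first, gap_ext):  # pragma: no cover - jitted
    L, M = scores.shape[0], code.shape[0]
    h_prev = np.zeros(M + 1)
    e_prev = np.full(M + 1, -1e30)
    best = 0.0
    for i in range(1, L + 1):
        h_cur = np.zeros(M + 1)
        e_cur = np.full(M + 1, -1e30)
        f = -1e30
        for j in range(1, M + 1):
            c = code[j - 1]
            s = scores[i - 1, c] if c >= 0 else 0.0
            e_cur[j] = max(h_prev[j] - gap_first, e_prev[j] - gap_ext)
            f = max(h_cur[j - 1] - gap_first, f - gap_ext)
            h = h_prev[j - 1] + s
            if e_cur[j] > h:
                h = e_cur[j]
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True)
def _sw_matrices(scores, code, gap_first, gap_ext):  # pragma: no cover - jitted
    L, M = scores.shape[0], code.shape[0]
    H = np.zeros((L + 1, M + 1))
    E = np.full((L + 1, M + 1), -1e30)
    F = np.full((L + 1, M + 1), -1e30)
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            c = code[j - 1]
            s = scores[i - 1, c] if c >= 0 else 0.0
            E[i, j] = max(H[i, j - 1] - gap_first, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_first, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _traceback(
    model: ProfileModel, code: np.ndarray
) -> tuple[float, tuple[int, int], tuple[int, int], tuple[int, ...]]:
    """Best local path: (score, model span, seq span, per-model-position map).

    In the alignment map, E-state columns (sequence insertions relative to the
    model) are dropped: the stacking is model-anchored.
    """
    gap_first = model.gap_open + model.gap_extend
    H, E, F = _sw_matrices(model.scores, code, gap_first, model.gap_extend)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    best = float(H[i, j])
    if best <= 0.0:
        return 0.0, (0, 0), (0, 0), ()
    model_end, seq_end = int(i), int(j)
    aligned: dict[int, int] = {}
    state = "H"
    eps = 1e-9
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= 0.0:
                break
            c = code[j - 1]
            s = model.scores[i - 1, c] if c >= 0 else 0.0
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
                aligned[i - 1] = j - 1
                i -= 1
                j -= 1
            elif abs(H[i, j] - E[i, j]) < eps:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in model: consume sequence residue
            if abs(E[i, j] - (E[i, j - 1] - model.gap_extend)) < eps:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F: gap in sequence: consume model position
            aligned[i - 1] = -1
            if abs(F[i, j] - (F[i - 1, j] - model.gap_extend)) < eps:
                i -= 1
            else:
                i -= 1
                state = "H"
    model_start, seq_start = int(i), int(j)
    mapping = tuple(
        aligned.get(pos, -1) for pos in range(model_start, model_end)
    )
    return best, (model_start, model_end), (seq_start, seq_end), mapping


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def build_profile(
    alignment: Sequence[str],
    model_id: str = "model",
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    z_constant: float = 2000.0,
) -> ProfileModel:
    """Build a profile from equal-length aligned rows ('-' for gaps).

    Columns with more than *max_gap_fraction* gaps are dropped.  Per kept
    column, residue probabilities get a Dirichlet pseudocount ``alpha`` per
    residue against the uniform background; scores are half-bit log-odds.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("alignment rows differ in length")
    n_rows = len(alignment)
    columns = []
    consensus = []
    for col in range(width):
        residues = [row[col] for row in alignment]
        n_gaps = sum(1 for r in residues if r == GAP)
        if n_gaps > max_gap_fraction * n_rows:
            continue
        counts = np.zeros(20)
        for r in residues:
            idx = _AA_INDEX.get(r)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        p = (counts + pseudocount) / (total + 20.0 * pseudocount)
        columns.append(2.0 * np.log2(p / _BACKGROUND))
        consensus.append(AMINO_ACIDS[int(np.argmax(counts))] if total else "X")
    if not columns:
        raise FamilyCollapseError(f"model {model_id!r}: all columns gap-dominated")
    return ProfileModel(
        model_id=model_id,
        scores=np.asarray(columns),
        gap_open=gap_open,
        gap_extend=gap_extend,
        z_constant=z_constant,
        consensus="".join(consensus),
    )


def calibrate(
    model: ProfileModel,
    decoy_count: int = 200,
    decoy_len: int = 350,
    seed: int = 0,
) -> ProfileModel:
    """Fit a Gumbel law to max local scores on i.i.d. random decoys."""
    rng = np.random.default_rng(seed)
    gap_first = model.gap_open + model.gap_extend
    maxima = np.empty(decoy_count)
    for d in range(decoy_count):
        code = rng.integers(0, 20, size=decoy_len).astype(np.int8)
        maxima[d] = _sw_score(model.scores, code, gap_first, model.gap_extend)
    loc, scale = gumbel_r.fit(maxima)
    if not np.isfinite(scale) or scale <= 0:
        raise CalibrationError(f"model {model.model_id!r}: degenerate Gumbel fit")
    return replace(model, gumbel_mu=float(loc), gumbel_lambda=float(1.0 / scale))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def score_sequence(model: ProfileModel, sequence: str) -> float:
    """Best local profile-vs-sequence score (no traceback)."""
    return float(
        _sw_score(
            model.scores,
            encode(sequence),
            model.gap_open + model.gap_extend,
            model.gap_extend,
        )
    )


def scan(
    model: ProfileModel,
    records: Sequence[ProteinRecord],
    max_evalue: float = 1e-4,
) -> list[ProfileHit]:
    """Best hit per sequence with E <= max_evalue, sorted by E then id."""
    if not model.calibrated:
        raise UncalibratedModelError(
            f"model {model.model_id!r} must be calibrated before scanning"
        )
    min_score = model.score_threshold(max_evalue)
    hits: list[ProfileHit] = []
    for record in records:
        code = encode(record.sequence)
        score = float(
            _sw_score(
                model.scores, code, model.gap_open + model.gap_extend, model.gap_extend
            )
        )
        if score <= 0.0 or score < min_score:
            continue
        evalue = model.evalue(score)
        if evalue > max_evalue:
            continue
        _, model_span, seq_span, mapping = _traceback(model, code)
        hits.append(
            ProfileHit(
                model_id=model.model_id,
                seq_id=record.id,
                score=score,
                evalue=evalue,
                span=Interval(record.id, seq_span[0], seq_span[1], model.model_id),
                model_span=model_span,
                aligned=mapping,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.seq_id))
    return hits


def stack_hits(
    model: ProfileModel,
    hits: Sequence[ProfileHit],
    records_by_id: Mapping[str, ProteinRecord],
) -> list[str]:
    """Model-anchored realignment: one row per hit over the model positions."""
    rows = []
    for hit in hits:
        seq = records_by_id[hit.seq_id].sequence
        row = [GAP] * model.length
        start = hit.model_span[0]
        for offset, seq_idx in enumerate(hit.aligned):
            if seq_idx >= 0:
                row[start + offset] = seq[seq_idx]
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------
# Iterative enrichment (profile search with inclusion rounds)
# ---------------------------------------------------------------------------

def _anchor_alignment(
    members: Sequence[ProteinRecord], scheme: ScoringScheme
) -> list[str]:
    """Initial alignment: stack members onto the longest member's positions."""
    anchor = max(members, key=lambda r: (len(r.sequence), r.id))
    rows = [anchor.sequence]
    for member in members:
        if member.id == anchor.id:
            continue
        result = local_align(member.sequence, anchor.sequence, scheme)
        row = [GAP] * len(anchor.sequence)
        if result.score > 0:
            aligner = scheme.aligner()
            alignment = next(iter(aligner.align(member.sequence, anchor.sequence)))
            blocks_member, blocks_anchor = alignment.aligned
            for (ms, me), (as_, ae) in zip(blocks_member, blocks_anchor):
                for k in range(me - ms):
                    row[as_ + k] = member.sequence[ms + k]
        rows.append("".join(row))
    return rows


def iterate_profile(
    seed_members: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    model_id: str,
    iterations: int = 5,
    inclusion_evalue: float = 1e-3,
    min_model_length: int = 10,
    decoy_count: int = 200,
    decoy_len: int = 350,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
) -> tuple[ProfileModel, set[str], list[str]]:
    """Iteratively enrich a seed cluster against a reduced database.

    Each round scans the database, adds sequences at the inclusion E-value,
    realigns all members to the model (stacking hit spans by model
    coordinates), rebuilds and recalibrates.  Membership is monotonically
    non-decreasing; iteration stops early once it is fixed.  Returns the final
    model, the member id set, and the final member alignment.
    """
    if not seed_members:
        raise ValueError("empty seed cluster")
    scheme = scheme or ScoringScheme()
    by_id: dict[str, ProteinRecord] = {r.id: r for r in seed_members}
    for record in database:
        by_id.setdefault(record.id, record)
    members: set[str] = {r.id for r in seed_members}

    alignment = _anchor_alignment(list(seed_members), scheme)
    model = build_profile(alignment, model_id=model_id)
    _check_length(model, min_model_length)
    model = calibrate(model, decoy_count=decoy_count, decoy_len=decoy_len, seed=seed)

    for round_no in range(1, iterations + 1):
        hits = scan(model, list(database), max_evalue=inclusion_evalue)
        new_members = members | {h.seq_id for h in hits}
        # realign the full membership to the current model
        member_records = [by_id[m] for m in sorted(new_members)]
        member_hits = scan(model, member_records, max_evalue=np.inf)
        recovered = {h.seq_id for h in member_hits}
        alignment = stack_hits(model, member_hits, by_id)
        if not alignment:
            raise FamilyCollapseError(f"model {model_id!r}: no members realigned")
        model = build_profile(alignment, model_id=model_id)
        _check_length(model, min_model_length)
        model = calibrate(
            model, decoy_count=decoy_count, decoy_len=decoy_len, seed=seed + round_no
        )
        fixed = new_members == members
        members = new_members
        if fixed:
            break
    return model, members, alignment


def _check_length(model: ProfileModel, min_model_length: int) -> None:
    if model.length < min_model_length:
        raise FamilyCollapseError(
            f"model {model.model_id!r} collapsed to {model.length} columns "
            f"(< {min_model_length})"
        )


# ---------------------------------------------------------------------------
# Overlap-driven cluster merging
# ---------------------------------------------------------------------------

def merge_overlapping_clusters(
    clusters: Mapping[str, set[str]],
    hits: Mapping[str, Sequence[ProfileHit]],
    min_shared: int = 2,
    min_overlap_frac: float = 0.5,
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Merge clusters whose profiles hit the same sequences at the same place.

    Two clusters merge when they share >= *min_shared* sequences on which
    their hit spans overlap by >= *min_overlap_frac* of the shorter span;
    merging is transitive (union-find).  Returns ``(member_ids,
    source_cluster_ids)`` per merged cluster, sorted by size then id.
    """
    ids = sorted(clusters)
    parent = {c: c for c in ids}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    spans: dict[str, dict[str, Interval]] = {
        c: {h.seq_id: h.span for h in hits.get(c, [])} for c in ids
    }
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = 0
            for seq_id in spans[a].keys() & spans[b].keys():
                sa, sb = spans[a][seq_id], spans[b][seq_id]
                shorter = min(len(sa), len(sb))
                if shorter and sa.overlap(sb) >= min_overlap_frac * shorter:
                    shared += 1
                    if shared >= min_shared:
                        break
            if shared >= min_shared:
                union(a, b)

    groups: dict[str, list[str]] = {}
    for c in ids:
        groups.setdefault(find(c), []).append(c)
    merged = [
        (
            frozenset().union(*(clusters[c] for c in group)),
            frozenset(group),
        )
        for group in groups.values()
    ]
    merged.sort(key=lambda pair: (-len(pair[0]), min(pair[1])))
    return merged


# ---------------------------------------------------------------------------
# Model file round-trip
# ---------------------------------------------------------------------------

def write_model(model: ProfileModel, path: str | Path) -> None:
    with open(path, "w") as handle:
        mu = "" if model.gumbel_mu is None else f"{model.gumbel_mu:.6f}"
        lam = "" if model.gumbel_lambda is None else f"{model.gumbel_lambda:.6f}"
        handle.write(
            f"#id={model.model_id}\tlength={model.length}\tmu={mu}\t"
            f"lambda={lam}\tZ={model.z_constant:g}\tgap_open={model.gap_open:g}\t"
            f"gap_extend={model.gap_extend:g}\tconsensus={model.consensus}\n"
        )
        for row in model.scores:
            handle.write("\t".join(f"{v:.4f}" for v in row) + "\n")


def read_model(path: str | Path) -> ProfileModel:
    with open(path) as handle:
        header = handle.readline().lstrip("#").rstrip("\n")
        meta = dict(tok.split("=", 1) for tok in header.split("\t"))
        scores = np.array(
            [[float(v) for v in line.split("\t")] for line in handle if line.strip()]
        )
    return ProfileModel(
        model_id=meta["id"],
        scores=scores,
        gap_open=float(meta["gap_open"]),
        gap_extend=float(meta["gap_extend"]),
        gumbel_mu=float(meta["mu"]) if meta["mu"] else None,
        gumbel_lambda=float(meta["lambda"]) if meta["lambda"] else None,
        z_constant=float(meta["Z"]),
        consensus=meta.get("consensus", ""),
    )
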