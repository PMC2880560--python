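"""Protein FASTA / TSV input-output, the completeness filter, and residue masking.

Records carry their provenance (metagenome vs genome), the genome's
environment-set label (related / unrelated to the target environment) and a
completeness flag for metagenome ORFs.  Metagenome FASTA has no standard field
for completeness, so it travels as a ``key=value`` token in the description
line (``partial=1`` marks an ORF that ran off the edge of its contig).

All coordinates are 0-based half-open.  Masked residues are written as ``'X'``;
downstream scorers give ``'X'`` a score of 0 against everything.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    FastaFormatError,
    IntervalBoundsError,
    InvalidResidueError,
    LabelError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: The 20 standard residues plus the mask character.
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}


class Origin(str, Enum):
    METAGENOME = "metagenome"
    GENOME = "genome"


class EnvironmentSet(str, Enum):
    RELATED = "related"
    UNRELATED = "unrelated"
    NONE = "none"


@dataclass(frozen=True)
class ProteinRecord:
    """One ORF or genome protein."""

    id: str
    sequence: str
    origin: Origin = Origin.METAGENOME
    genome_id: str | None = None
    environment_set: EnvironmentSet = EnvironmentSet.NONE
    complete: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidResidueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise InvalidResidueError(
                f"record {self.id!r} contains invalid residues {sorted(bad)}"
            )
        if self.origin is Origin.GENOME and self.genome_id is None:
            raise LabelError(f"genome record {self.id!r} lacks a genome_id")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A half-open [start, end) segment on a sequence, tagged by the model
    whose hit produced it."""

    seq_id: str
    start: int
    end: int
    source_model: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalBoundsError(
                f"interval [{self.start}, {self.end}) on {self.seq_id!r} is empty "
                "or negative"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared residues with another interval (same sequence)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# FASTA and TSV round-trips
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, EnvironmentSet]:
    """Read a two-column TSV (genome_id, set in {related, unrelated})."""
    labels: dict[str, EnvironmentSet] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            genome_id, label = row[0], row[1]
            try:
                labels[genome_id] = EnvironmentSet(label)
            except ValueError:
                raise LabelError(f"unknown environment set {label!r} for {genome_id!r}")
    return labels


def _parse_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for word in description.split():
        if "=" in word:
            key, _, value = word.partition("=")
            tokens[key] = value
    return tokens


def read_fasta(
    path: str | Path,
    origin: Origin | str = Origin.METAGENOME,
    labels: Mapping[str, EnvironmentSet] | None = None,
) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects, order-preserving.

    Description tokens understood: ``partial=1`` / ``complete=0`` mark an
    incomplete ORF; ``genome=<id>`` attaches the source genome, which must be
    present in *labels* when given.  Duplicate ids are rejected.
    """
    origin = Origin(origin)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        tokens = _parse_tokens(rec.description)
        complete = not (tokens.get("partial") == "1" or tokens.get("complete") == "0")
        genome_id = tokens.get("genome")
        env = EnvironmentSet.NONE
        if genome_id is not None and labels is not None:
            if genome_id not in labels:
                raise LabelError(f"genome {genome_id!r} missing from label table")
            env = labels[genome_id]
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                origin=origin,
                genome_id=genome_id,
                environment_set=env,
                complete=complete,
                description=rec.description.partition(" ")[2],
            )
        )
    if not records:
        # Distinguish an empty file from a non-FASTA file is not worth the
        # trouble here; empty input is legal.
        pass
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with their provenance tokens in the description."""
    out = []
    for record in records:
        tokens = []
        if record.genome_id is not None:
            tokens.append(f"genome={record.genome_id}")
        if not record.complete:
            tokens.append("partial=1")
        if record.description:
            tokens.append(record.description)
        out.append(
            SeqRecord(Seq(record.sequence), id=record.id, description=" ".join(tokens))
        )
    SeqIO.write(out, path if hasattr(path, "write") else str(path), "fasta")


def read_intervals(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            intervals.append(Interval(row[0], int(row[1]), int(row[2]), row[3]))
    return intervals


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        for iv in intervals:
            writer.writerow([iv.seq_id, iv.start, iv.end, iv.source_model])


# ---------------------------------------------------------------------------
# Completeness filter and masking
# ---------------------------------------------------------------------------

def filter_complete_orfs(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], int]:
    """Keep exactly the ``complete=True`` records, order preserved.

    Returns the kept records and the number removed (incomplete ORFs that ran
    off the edge of their contig are dropped before any clustering).
    """
    kept = [r for r in records if r.complete]
    return kept, len(records) - len(kept)


def apply_masks(
    records: Sequence[ProteinRecord], intervals: Sequence[Interval]
) -> list[ProteinRecord]:
    """Replace masked positions by 'X'.  Idempotent; overlaps mask the union."""
    by_seq: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    out = []
    for record in records:
        ivs = by_seq.get(record.id)
        if not ivs:
            out.append(record)
            continue
        seq = list(record.sequence)
        for iv in ivs:
            if iv.end > len(seq):
                raise IntervalBoundsError(
                    f"interval [{iv.start}, {iv.end}) exceeds length "
                    f"{len(seq)} of {record.id!r}"
                )
            seq[iv.start : iv.end] = "X" * (iv.end - iv.start)
        out.append(replace(record, sequence="".join(seq)))
    return out


def unmasked_length(record: ProteinRecord) -> int:
    """Residues not masked out (everything that is not 'X')."""
    return len(record.sequence) - record.sequence.count("X")
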