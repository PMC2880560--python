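"""The quantitative filter cascade reducing raw families to curated
candidates, plus advisory curation flags.

Each stage removes families for one documented reason and emits a
:class:`FilterReport`; the final human-style curation criteria are emitted as
boolean flags only, never auto-applied.  Boundary semantics are literal:
"more than 20%" is strict, "at least 75%" / "shorter than 100" / "fewer than
10" / "less than 15" give inclusive keeps at 20%, 75%, 100, 10 and 15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .family_discovery import Family
from .profile_models import GAP, ProfileModel, scan
from .sequence_io import Interval, ProteinRecord


@dataclass
class FilterReport:
    stage_name: str
    families_in: int
    families_out: int
    removed: dict[str, str] = field(default_factory=dict)  # family_id -> reason

    def __post_init__(self) -> None:
        assert self.families_out == self.families_in - len(self.removed)


def _split(
    families: Sequence[Family], removed: Mapping[str, str], stage: str
) -> tuple[list[Family], FilterReport]:
    kept = [f for f in families if f.family_id not in removed]
    for family in kept:
        family.provenance.append(f"passed {stage}")
    return kept, FilterReport(stage, len(families), len(kept), dict(removed))


def drop_no_rescan_hits(
    families: Sequence[Family],
    metagenome: Sequence[ProteinRecord],
    max_evalue: float = 1e-4,
) -> tuple[list[Family], FilterReport]:
    """Remove families whose model finds no metagenome hit at the cutoff."""
    removed = {}
    for family in families:
        if not scan(family.model, list(metagenome), max_evalue=max_evalue):
            removed[family.family_id] = "no metagenome rescan hits"
    return _split(families, removed, "rescan")


def drop_known_linked(
    families: Sequence[Family],
    known_models: Sequence[ProfileModel],
    max_evalue: float = 1e-3,
) -> tuple[list[Family], FilterReport]:
    """Remove families likely to be branches of known annotated families.

    Profile-profile comparison is approximated by scanning each family's
    consensus sequence with every known model.
    """
    removed = {}
    for family in families:
        consensus = ProteinRecord(
            id=f"{family.family_id}_consensus", sequence=family.model.consensus
        )
        for known in known_models:
            if scan(known, [consensus], max_evalue=max_evalue):
                removed[family.family_id] = f"linked to known model {known.model_id}"
                break
    return _split(families, removed, "known-linked")


def drop_known_overlap(
    families: Sequence[Family],
    known_hit_intervals: Sequence[Interval],
    max_frac: float = 0.20,
) -> tuple[list[Family], FilterReport]:
    """Remove families overlapping one known family on > max_frac of members.

    For each family and each known model, the fraction of member sequences on
    which the family hit span and the known hit span share at least one
    residue; strictly greater than the threshold removes the family.
    """
    by_seq_model: dict[tuple[str, str], list[Interval]] = {}
    for iv in known_hit_intervals:
        by_seq_model.setdefault((iv.seq_id, iv.source_model), []).append(iv)
    known_model_ids = {iv.source_model for iv in known_hit_intervals}

    removed = {}
    for family in families:
        if not family.members:
            continue
        for known_id in sorted(known_model_ids):
            overlapping = 0
            for hit in family.members:
                ivs = by_seq_model.get((hit.seq_id, known_id), ())
                if any(hit.span.overlap(iv) >= 1 for iv in ivs):
                    overlapping += 1
            if overlapping / len(family.members) > max_frac:
                removed[family.family_id] = (
                    f"overlaps known model {known_id} on "
                    f"{overlapping}/{len(family.members)} members"
                )
                break
    return _split(families, removed, "known-overlap")


def require_genomic_coverage(
    families: Sequence[Family],
    genome_proteomes: Mapping[str, Sequence[ProteinRecord]],
    min_frac: float = 0.75,
    max_evalue: float = 1e-4,
) -> tuple[list[Family], FilterReport]:
    """Keep a family only if some genome protein is covered >= min_frac by a
    hit of the family model (guards against fragment clusters)."""
    all_proteins = [p for proteome in genome_proteomes.values() for p in proteome]
    by_id = {p.id: p for p in all_proteins}
    removed = {}
    for family in families:
        hits = scan(family.model, all_proteins, max_evalue=max_evalue)
        best = 0.0
        for hit in hits:
            coverage = len(hit.span) / len(by_id[hit.seq_id].sequence)
            best = max(best, coverage)
        if best < min_frac:
            removed[family.family_id] = (
                f"best genome-protein coverage {best:.2f} < {min_frac:.2f}"
            )
    return _split(families, removed, "genomic-coverage")


def require_model_length(
    families: Sequence[Family], min_len: int = 100
) -> tuple[list[Family], FilterReport]:
    """Keep families whose model has at least min_len positions."""
    removed = {
        f.family_id: f"model length {f.model.length} < {min_len}"
        for f in families
        if f.model.length < min_len
    }
    return _split(families, removed, "model-length")


def require_min_metagenome_hits(
    families: Sequence[Family],
    metagenome: Sequence[ProteinRecord],
    min_hits: int = 10,
    max_evalue: float = 1e-4,
) -> tuple[list[Family], FilterReport]:
    """Keep families with at least min_hits metagenome hits at the cutoff."""
    removed = {}
    for family in families:
        n = len(scan(family.model, list(metagenome), max_evalue=max_evalue))
        if n < min_hits:
            removed[family.family_id] = f"{n} metagenome hits < {min_hits}"
    return _split(families, removed, "min-metagenome-hits")


def run_cascade(
    families: Sequence[Family],
    metagenome: Sequence[ProteinRecord],
    known_models: Sequence[ProfileModel],
    known_hit_intervals: Sequence[Interval],
    genome_proteomes: Mapping[str, Sequence[ProteinRecord]],
    known_overlap_frac: float = 0.20,
    genomic_coverage_frac: float = 0.75,
    min_model_length: int = 100,
    min_metagenome_hits: int = 10,
    counting_evalue: float = 1e-4,
) -> tuple[list[Family], list[FilterReport]]:
    """The full cascade in publication order; reports per stage."""
    reports = []
    families, report = drop_no_rescan_hits(families, metagenome, counting_evalue)
    reports.append(report)
    families, report = drop_known_linked(families, known_models)
    reports.append(report)
    families, report = drop_known_overlap(
        families, known_hit_intervals, known_overlap_frac
    )
    reports.append(report)
    families, report = require_genomic_coverage(
        families, genome_proteomes, genomic_coverage_frac, counting_evalue
    )
    reports.append(report)
    families, report = require_model_length(families, min_model_length)
    reports.append(report)
    families, report = require_min_metagenome_hits(
        families, metagenome, min_metagenome_hits, counting_evalue
    )
    reports.append(report)
    return list(families), reports


# ---------------------------------------------------------------------------
# Advisory curation flags
# ---------------------------------------------------------------------------

_FUNCTION_KEYWORDS = (
    "transporter", "kinase", "synthase", "synthetase", "hydrolase",
    "transferase", "reductase", "oxidase", "polymerase", "permease",
    "protease", "peptidase", "ligase", "phosphatase", "receptor",
    "regulator", "integrase", "transposase", "dehydrogenase",
)


def window_entropy(sequence: str, window: int = 12) -> np.ndarray:
    """Shannon entropy (bits) of each length-*window* segment."""
    n = len(sequence) - window + 1
    if n <= 0:
        return np.empty(0)
    out = np.empty(n)
    for i in range(n):
        _, counts = np.unique(list(sequence[i : i + window]), return_counts=True)
        p = counts / window
        out[i] = float(-(p * np.log2(p)).sum())
    return out


def low_complexity_fraction(
    sequence: str, window: int = 12, entropy_threshold: float = 2.0
) -> float:
    """Fraction of residues inside a low-entropy window."""
    entropies = window_entropy(sequence, window)
    if entropies.size == 0:
        return 0.0
    low = np.zeros(len(sequence), dtype=bool)
    for i in np.flatnonzero(entropies < entropy_threshold):
        low[i : i + window] = True
    return float(low.mean())


def curation_flags(
    family: Family,
    reference_db: Sequence[ProteinRecord] | None = None,
    member_descriptions: Mapping[str, str] | None = None,
    min_conservation: float = 0.5,
    max_low_complexity: float = 0.3,
    min_core_frac: float = 0.5,
    min_reference_hits: int = 15,
    max_evalue: float = 1e-4,
) -> dict[str, bool]:
    """Boolean curation flags; advisory only, nothing is removed here.

    * ``divergent`` — no alignment column reaches the conservation floor, or
      the members carry too many low-complexity residues;
    * ``no_core`` — fewer than half the members overlap a common model region;
    * ``few_reference_hits`` — sparse support in the reference database;
    * ``annotatable`` — member descriptions carry function keywords.
    """
    rows = family.alignment
    flags = {
        "divergent": False,
        "no_core": False,
        "few_reference_hits": False,
        "annotatable": False,
    }

    if rows:
        width = len(rows[0])
        best_conservation = 0.0
        for col in range(width):
            residues = [row[col] for row in rows if row[col] != GAP]
            if not residues:
                continue
            top = max(residues.count(r) for r in set(residues))
            best_conservation = max(best_conservation, top / len(rows))
        low_fracs = [
            low_complexity_fraction(row.replace(GAP, "")) for row in rows
            if row.replace(GAP, "")
        ]
        mean_low = float(np.mean(low_fracs)) if low_fracs else 0.0
        if best_conservation < min_conservation or mean_low > max_low_complexity:
            flags["divergent"] = True

        # core: the model position covered by the most members
        coverage = np.zeros(width)
        for row in rows:
            for col in range(width):
                if row[col] != GAP:
                    coverage[col] += 1
        if width and coverage.max() < min_core_frac * len(rows):
            flags["no_core"] = True

    if reference_db is not None:
        n_ref = len(scan(family.model, list(reference_db), max_evalue=max_evalue))
        if n_ref < min_reference_hits:
            flags["few_reference_hits"] = True

    if member_descriptions:
        described = [
            member_descriptions.get(h.seq_id, "").lower() for h in family.members
        ]
        annotated = sum(
            1 for d in described if any(k in d for k in _FUNCTION_KEYWORDS)
        )
        if family.members and annotated / len(family.members) >= 0.25:
            flags["annotatable"] = True

    return flags
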