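"""Family discovery orchestration: mask known families, accept
previously-seen-but-uncharacterized families, cluster the remainder into
novel families.

The order matters: known-family hits are masked first so neither the prior
seed search nor the de-novo clustering rediscovers annotated domains; the
intervals are kept for the downstream known-overlap filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .errors import FamilyCollapseError
from .mcl_clustering import mcl
from .profile_models import (
    ProfileHit,
    ProfileModel,
    build_profile,
    calibrate,
    iterate_profile,
    merge_overlapping_clusters,
    scan,
    stack_hits,
)
from .sequence_io import Interval, ProteinRecord, apply_masks, unmasked_length
from .similarity import ScoringScheme, alignment_score, build_graph


class FamilyCategory(str, Enum):
    KNOWN = "known"
    UNCHARACTERIZED_PRIOR = "uncharacterized_prior"
    NOVEL = "novel"


@dataclass
class Family:
    family_id: str
    category: FamilyCategory
    members: list[ProfileHit]
    model: ProfileModel
    alignment: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> set[str]:
        return {h.seq_id for h in self.members}


def mask_known(
    metagenome: Sequence[ProteinRecord],
    known_models: Sequence[ProfileModel],
    max_evalue: float = 1e-4,
) -> tuple[list[ProteinRecord], list[Interval]]:
    """Scan with the known-family models and mask every hit span.

    Returns the masked records plus the hit intervals (retained for the
    known-overlap filter later in the cascade).
    """
    intervals: list[Interval] = []
    for model in known_models:
        for hit in scan(model, list(metagenome), max_evalue=max_evalue):
            intervals.append(hit.span)
    return apply_masks(metagenome, intervals), intervals


def accept_prior_families(
    masked_metagenome: Sequence[ProteinRecord],
    prior_seed_sets: Mapping[str, Sequence[str]],
    min_seed_hits: int = 15,
    min_score: float = 60.0,
    scheme: ScoringScheme | None = None,
    calibration_seed: int = 0,
    max_evalue: float = 1e-4,
) -> tuple[list[Family], list[ProteinRecord]]:
    """Accept prior (seen-but-uncharacterized) families with enough support.

    Seed sequences are searched against the masked metagenome by pairwise
    alignment at the score threshold; a family with at least *min_seed_hits*
    distinct metagenome hits is accepted, given a profile model built from
    its hits, and its hit spans are masked before novel discovery.
    """
    scheme = scheme or ScoringScheme()
    records = list(masked_metagenome)
    by_id = {r.id: r for r in records}
    families: list[Family] = []
    for offset, (seed_id, seeds) in enumerate(sorted(prior_seed_sets.items())):
        hit_ids = set()
        for record in records:
            if any(
                alignment_score(record.sequence, seed, scheme) >= min_score
                for seed in seeds
            ):
                hit_ids.add(record.id)
        if len(hit_ids) < min_seed_hits:
            continue
        anchor = max(seeds, key=len)
        seed_records = [
            ProteinRecord(id=f"{seed_id}_seed", sequence=anchor)
        ] + [by_id[i] for i in sorted(hit_ids)]
        try:
            model, _, alignment = iterate_profile(
                seed_records,
                database=[by_id[i] for i in sorted(hit_ids)],
                model_id=seed_id,
                iterations=1,
                seed=calibration_seed + offset,
                scheme=scheme,
            )
        except FamilyCollapseError:
            continue
        hits = scan(model, records, max_evalue=max_evalue)
        families.append(
            Family(
                family_id=seed_id,
                category=FamilyCategory.UNCHARACTERIZED_PRIOR,
                members=hits,
                model=model,
                alignment=alignment,
                provenance=[f"accepted with {len(hit_ids)} seed hits"],
            )
        )
        records = apply_masks(records, [h.span for h in hits])
        by_id = {r.id: r for r in records}
    return families, records


def discover_novel(
    masked_metagenome: Sequence[ProteinRecord],
    nr85s: Sequence[ProteinRecord],
    min_edge_score: float = 60.0,
    inflation: float = 2.0,
    psi_iterations: int = 5,
    inclusion_evalue: float = 1e-3,
    min_unmasked: int = 30,
    decoy_count: int = 200,
    decoy_len: int = 350,
    calibration_seed: int = 0,
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
) -> list[Family]:
    """De-novo family construction on the masked metagenome.

    Similarity graph at the score threshold -> Markov clustering ->
    per-cluster iterative profile enrichment over the reduced database ->
    merging of clusters with overlapping hits.
    """
    scheme = scheme or ScoringScheme()
    usable = [r for r in masked_metagenome if unmasked_length(r) >= min_unmasked]
    if not usable:
        return []
    edges = build_graph(
        usable, scheme, min_score=min_edge_score, prefilter=prefilter
    )
    partition = mcl(edges, nodes=[r.id for r in usable], inflation=inflation)
    by_id = {r.id: r for r in usable}

    raw: dict[str, tuple[ProfileModel, set[str], list[str]]] = {}
    for index, cluster in enumerate(partition.non_singletons):
        family_id = f"NOV{index:04d}"
        seed_records = [by_id[i] for i in sorted(cluster)]
        try:
            model, members, alignment = iterate_profile(
                seed_records,
                database=list(nr85s),
                model_id=family_id,
                iterations=psi_iterations,
                inclusion_evalue=inclusion_evalue,
                decoy_count=decoy_count,
                decoy_len=decoy_len,
                seed=calibration_seed + index,
                scheme=scheme,
            )
        except FamilyCollapseError:
            continue
        raw[family_id] = (model, members, alignment)

    # merge clusters whose profiles hit the same metagenome spans
    hits_by_family = {
        fid: scan(model, usable, max_evalue=1e-4)
        for fid, (model, _, _) in raw.items()
    }
    merged = merge_overlapping_clusters(
        {fid: set(members) for fid, (_, members, _) in raw.items()},
        hits_by_family,
    )

    families: list[Family] = []
    for index, (member_ids, sources) in enumerate(merged):
        if len(sources) == 1:
            source = next(iter(sources))
            family_id = source
            model, _, alignment = raw[source]
            hits = hits_by_family[source]
            provenance = [f"from cluster {source}"]
        else:
            family_id = f"MRG{index:04d}"
            # rebuild a joint model from the union of members
            seed_records = [by_id[i] for i in sorted(member_ids) if i in by_id]
            try:
                model, _, alignment = iterate_profile(
                    seed_records,
                    database=list(nr85s),
                    model_id=family_id,
                    iterations=1,
                    decoy_count=decoy_count,
                    decoy_len=decoy_len,
                    seed=calibration_seed + 10_000 + index,
                    scheme=scheme,
                )
            except FamilyCollapseError:
                continue
            hits = scan(model, usable, max_evalue=1e-4)
            provenance = [f"merged from {sorted(sources)}"]
        families.append(
            Family(
                family_id=family_id,
                category=FamilyCategory.NOVEL,
                members=hits,
                model=model,
                alignment=alignment,
                provenance=provenance,
            )
        )
    return families
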