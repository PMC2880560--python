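"""End-to-end orchestration of the discovery + filtering + statistics run.

``run_pipeline`` executes: completeness filter -> known-family masking ->
prior-family acceptance -> de-novo discovery -> filter cascade -> counting
against the labelled genome collections -> Ov/Ex/Es scoring, rankings and
figure-style reports.  Every stage logs its input/output counts; a rerun with
the same configuration and seed writes byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError
from .family_discovery import (
    Family,
    FamilyCategory,
    accept_prior_families,
    discover_novel,
    mask_known,
)
from .family_filters import FilterReport, curation_flags, run_cascade
from .mcl_clustering import cluster_size_histogram, mcl
from .profile_models import ProfileModel, build_profile, calibrate, write_model
from .sequence_io import (
    EnvironmentSet,
    Interval,
    ProteinRecord,
    filter_complete_orfs,
    write_fasta,
    write_intervals,
)
from .similarity import ScoringScheme, reduce_identity
from .specificity_stats import (
    DatasetTotals,
    coverage_report,
    count_hits,
    es_histogram,
    format_scores,
    rank_families,
    score_table,
)

logger = logging.getLogger("envfam")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, at the published defaults."""

    min_edge_score: float = 60.0
    inflation: float = 2.0
    psi_iterations: int = 5
    inclusion_evalue: float = 1e-3
    counting_evalue: float = 1e-4
    z_constant: float = 2000.0
    identity_reduction: float = 0.85
    min_seed_hits: int = 15
    known_overlap_frac: float = 0.20
    genomic_coverage_frac: float = 0.75
    min_model_length: int = 100
    min_metagenome_hits: int = 10
    min_family_size: int = 10
    min_unmasked: int = 30
    decoy_count: int = 200
    decoy_len: int = 350
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_edge_score <= 0:
            raise ConfigurationError("min_edge_score must be positive")
        if not 0 < self.identity_reduction <= 1:
            raise ConfigurationError("identity_reduction must be in (0, 1]")
        for name in ("inclusion_evalue", "counting_evalue"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.inflation <= 1:
            raise ConfigurationError("inflation must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


@dataclass
class PipelineResult:
    families: list[Family]
    reports: list[FilterReport]
    counts: pd.DataFrame
    scores: pd.DataFrame
    totals: DatasetTotals
    known_intervals: list[Interval]
    flags: dict[str, dict[str, bool]]
    coverage: dict[str, dict[str, float]]


def build_known_models(
    known_seed_alignments: Mapping[str, Sequence[str]],
    config: PipelineConfig,
) -> list[ProfileModel]:
    """Profile models for the known-family library, calibrated."""
    models = []
    for offset, (family_id, rows) in enumerate(sorted(known_seed_alignments.items())):
        model = build_profile(
            list(rows), model_id=family_id, z_constant=config.z_constant
        )
        models.append(
            calibrate(
                model,
                decoy_count=config.decoy_count,
                decoy_len=config.decoy_len,
                seed=config.rng_seed + 70_000 + offset,
            )
        )
    return models


def run_pipeline(
    config: PipelineConfig,
    metagenome: Sequence[ProteinRecord],
    genomes: Mapping[str, Sequence[ProteinRecord]],
    labels: Mapping[str, EnvironmentSet],
    known_seed_alignments: Mapping[str, Sequence[str]] | None = None,
    prior_seed_sets: Mapping[str, Sequence[str]] | None = None,
    totals: DatasetTotals | None = None,
    out_dir: str | Path | None = None,
    apply_cascade: bool = True,
) -> PipelineResult:
    """Run the whole analysis; optionally write every intermediate table."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    scheme = ScoringScheme()

    complete, n_removed = filter_complete_orfs(list(metagenome))
    logger.info("completeness filter: %d -> %d ORFs", len(metagenome), len(complete))

    known_models = build_known_models(known_seed_alignments or {}, config)
    masked, known_intervals = mask_known(
        complete, known_models, max_evalue=config.counting_evalue
    )
    logger.info(
        "known masking: %d models, %d hit intervals",
        len(known_models),
        len(known_intervals),
    )

    prior_families: list[Family] = []
    if prior_seed_sets:
        prior_families, masked = accept_prior_families(
            masked,
            prior_seed_sets,
            min_seed_hits=config.min_seed_hits,
            min_score=config.min_edge_score,
            scheme=scheme,
            calibration_seed=config.rng_seed + 30_000,
            max_evalue=config.counting_evalue,
        )
        logger.info("prior families accepted: %d", len(prior_families))

    nr85s, _ = reduce_identity(
        masked, threshold=config.identity_reduction, scheme=scheme
    )
    logger.info("reduced database: %d -> %d sequences", len(masked), len(nr85s))

    novel = discover_novel(
        masked,
        nr85s,
        min_edge_score=config.min_edge_score,
        inflation=config.inflation,
        psi_iterations=config.psi_iterations,
        inclusion_evalue=config.inclusion_evalue,
        min_unmasked=config.min_unmasked,
        decoy_count=config.decoy_count,
        decoy_len=config.decoy_len,
        calibration_seed=config.rng_seed + 50_000,
        scheme=scheme,
    )
    logger.info("novel families discovered: %d", len(novel))

    families = prior_families + novel
    reports: list[FilterReport] = []
    if apply_cascade and families:
        families, reports = run_cascade(
            families,
            complete,
            known_models,
            known_intervals,
            genomes,
            known_overlap_frac=config.known_overlap_frac,
            genomic_coverage_frac=config.genomic_coverage_frac,
            min_model_length=config.min_model_length,
            min_metagenome_hits=config.min_metagenome_hits,
            counting_evalue=config.counting_evalue,
        )
        for report in reports:
            logger.info(
                "cascade %s: %d -> %d",
                report.stage_name,
                report.families_in,
                report.families_out,
            )

    if totals is None:
        totals = DatasetTotals(
            g_T=max(
                1,
                sum(
                    len(p)
                    for gid, p in genomes.items()
                    if labels[gid] is EnvironmentSet.RELATED
                ),
            ),
            n_T=max(
                1,
                sum(
                    len(p)
                    for gid, p in genomes.items()
                    if labels[gid] is EnvironmentSet.UNRELATED
                ),
            ),
            G_T=max(
                1,
                sum(1 for gid in genomes if labels[gid] is EnvironmentSet.RELATED),
            ),
            N_T=max(
                1,
                sum(1 for gid in genomes if labels[gid] is EnvironmentSet.UNRELATED),
            ),
        )

    if families:
        counts = count_hits(
            [f.model for f in families],
            genomes,
            labels,
            max_evalue=config.counting_evalue,
        )
        scores = score_table(counts, totals)
    else:
        counts = pd.DataFrame(columns=["g", "n", "G", "N"])
        counts.index.name = "family_id"
        scores = counts.assign(ov=[], ex=[], es=[])

    flags = {f.family_id: curation_flags(f) for f in families}

    # coverage: fractions of each protein set assigned to known vs new families
    known_hit_ids = {iv.seq_id for iv in known_intervals}
    new_hit_ids = {h.seq_id for f in families for h in f.members}
    coverage = {
        "metagenome": coverage_report(list(complete), known_hit_ids, new_hit_ids)
    }

    result = PipelineResult(
        families=families,
        reports=reports,
        counts=counts,
        scores=scores,
        totals=totals,
        known_intervals=known_intervals,
        flags=flags,
        coverage=coverage,
    )
    if out is not None:
        _write_run(result, out)
    return result


def _write_run(result: PipelineResult, out: Path) -> None:
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    format_scores(result.scores).to_csv(out / "scores.tsv", sep="\t")
    for by in ("ov", "ex", "es"):
        rank_families(result.scores, by=by).to_csv(
            out / f"ranking_{by}.tsv", sep="\t", index=False
        )
    es_histogram(result.scores).to_csv(out / "es_histogram.tsv", sep="\t", index=False)
    with open(out / "cascade_report.tsv", "w") as handle:
        handle.write("stage\tfamilies_in\tfamilies_out\n")
        for report in result.reports:
            handle.write(
                f"{report.stage_name}\t{report.families_in}\t{report.families_out}\n"
            )
    with open(out / "removals.tsv", "w") as handle:
        handle.write("family_id\tstage\treason\n")
        for report in result.reports:
            for family_id, reason in sorted(report.removed.items()):
                handle.write(f"{family_id}\t{report.stage_name}\t{reason}\n")
    with open(out / "flags.tsv", "w") as handle:
        handle.write("family_id\tdivergent\tno_core\tfew_reference_hits\tannotatable\n")
        for family_id, flagset in sorted(result.flags.items()):
            handle.write(
                family_id
                + "\t"
                + "\t".join(
                    str(int(flagset[k]))
                    for k in ("divergent", "no_core", "few_reference_hits", "annotatable")
                )
                + "\n"
            )
    with open(out / "coverage.json", "w") as handle:
        json.dump(result.coverage, handle, indent=2, sort_keys=True)
    write_intervals(result.known_intervals, out / "known_hits.tsv")
    family_dir = out / "families"
    family_dir.mkdir(exist_ok=True)
    for family in result.families:
        write_model(family.model, family_dir / f"{family.family_id}.model.tsv")
        with open(family_dir / f"{family.family_id}.members.tsv", "w") as handle:
            handle.write("seq_id\tscore\tevalue\tstart\tend\n")
            for hit in family.members:
                handle.write(
                    f"{hit.seq_id}\t{hit.score:.2f}\t{hit.evalue:.3g}\t"
                    f"{hit.span.start}\t{hit.span.end}\n"
                )
        with open(family_dir / f"{family.family_id}.provenance.jsonl", "w") as handle:
            for event in family.provenance:
                handle.write(json.dumps({"family": family.family_id, "event": event}) + "\n")


def stats_only(counts: pd.DataFrame, totals: DatasetTotals) -> pd.DataFrame:
    """Ov/Ex/Es on an externally supplied (g, n, G, N) table, 2-decimal form."""
    return format_scores(score_table(counts, totals))
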