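"""Synthetic world generator: a scaled-down metagenome plus related/unrelated
genome collections with planted protein families of known prevalence.

The generator emulates the statistical structure of a real environment study:
each planted family is a consensus sequence whose members are independent
per-site mutants; environment-specific families occur only in the related
genome set; per-genome copy numbers follow a zero-truncated geometric law
(heavy right tail); the metagenome is a sample of the related genomes'
proteins with a fraction truncated and flagged incomplete, plus i.i.d. random
singleton decoys.  A truth manifest maps every family-derived sequence to its
family, so every downstream stage can be scored against ground truth without
any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError
from .sequence_io import (
    AMINO_ACIDS,
    EnvironmentSet,
    Origin,
    ProteinRecord,
    write_fasta,
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    ``n_related_genomes``/``n_unrelated_genomes`` stand in for the study's
    environment-related and control genome collections.  Fractions are all in
    [0, 1]; counts positive.  The same seed always produces a byte-identical
    world.
    """

    n_related_genomes: int = 16
    n_unrelated_genomes: int = 48
    proteins_per_genome: int = 30
    n_metagenome_orfs: int = 800
    n_planted_families: int = 40
    frac_env_specific: float = 0.25
    frac_known: float = 0.0
    singleton_fraction: float = 0.06
    incomplete_orf_fraction: float = 0.2
    mutation_rate_per_site: float = 0.15
    copy_number_mean: float = 1.5
    consensus_length_range: tuple[int, int] = (90, 180)
    prevalence_range: tuple[float, float] = (0.6, 0.95)
    known_seed_depth: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_related_genomes",
            "n_unrelated_genomes",
            "proteins_per_genome",
            "n_metagenome_orfs",
            "n_planted_families",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "frac_env_specific",
            "frac_known",
            "singleton_fraction",
            "incomplete_orf_fraction",
            "mutation_rate_per_site",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.copy_number_mean < 1.0:
            raise ConfigurationError("copy_number_mean must be >= 1")
        lo, hi = self.consensus_length_range
        if lo < 60 or hi < lo:
            raise ConfigurationError(
                "consensus_length_range must satisfy 60 <= lo <= hi"
            )


@dataclass(frozen=True)
class PlantedFamily:
    family_id: str
    consensus: str
    prevalence_related: float
    prevalence_unrelated: float
    mean_copies: float
    is_known: bool

    def __post_init__(self) -> None:
        if len(self.consensus) < 60:
            raise ConfigurationError("consensus length must be >= 60")
        if not 0.0 <= self.prevalence_related <= 1.0:
            raise ConfigurationError("prevalence_related must be in [0, 1]")
        if not 0.0 <= self.prevalence_unrelated <= 1.0:
            raise ConfigurationError("prevalence_unrelated must be in [0, 1]")


@dataclass
class World:
    """A generated world: metagenome + labelled proteomes + ground truth."""

    config: WorldConfig
    metagenome: list[ProteinRecord]
    genomes: dict[str, list[ProteinRecord]]
    labels: dict[str, EnvironmentSet]
    families: list[PlantedFamily]
    #: member sequence id -> family id, for every family-derived sequence
    manifest: dict[str, str]
    #: aligned (gap-free) seed alignments for families flagged as known
    known_seed_alignments: dict[str, list[str]]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, 20, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    """Uniform replacement to any *other* residue with per-site probability."""
    seq = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < rate
    n = int(hit.sum())
    if n:
        current = seq[hit]
        # draw from the 19 alternatives by shifting past the current residue
        offsets = rng.integers(1, 20, size=n)
        idx = (np.searchsorted(_AA, current) + offsets) % 20
        seq[hit] = _AA[idx]
    return seq.tobytes().decode()


def _zt_geometric(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated geometric copy counts with the given mean (>= 1)."""
    if mean <= 1.0:
        return np.ones(size, dtype=int)
    return rng.geometric(1.0 / mean, size=size)


def generate_world(config: WorldConfig) -> World:
    """Generate the full synthetic world deterministically from the seed."""
    rng = np.random.default_rng(config.rng_seed)

    n_fam = config.n_planted_families
    n_specific = int(round(config.frac_env_specific * n_fam))
    n_known = int(round(config.frac_known * n_fam))
    lo, hi = config.consensus_length_range
    plo, phi = config.prevalence_range

    families: list[PlantedFamily] = []
    for i in range(n_fam):
        length = int(rng.integers(lo, hi + 1))
        prevalence = float(rng.uniform(plo, phi))
        env_specific = i < n_specific
        families.append(
            PlantedFamily(
                family_id=f"FAM{i:04d}",
                consensus=_random_sequence(rng, length),
                prevalence_related=prevalence,
                # habitat generalists are equally prevalent in both sets
                prevalence_unrelated=0.0 if env_specific else prevalence,
                mean_copies=config.copy_number_mean,
                is_known=i >= n_fam - n_known,
            )
        )

    labels: dict[str, EnvironmentSet] = {}
    genomes: dict[str, list[ProteinRecord]] = {}
    manifest: dict[str, str] = {}

    genome_plan = [
        (f"HGR{g:03d}", EnvironmentSet.RELATED)
        for g in range(config.n_related_genomes)
    ] + [
        (f"HGU{g:03d}", EnvironmentSet.UNRELATED)
        for g in range(config.n_unrelated_genomes)
    ]
    for genome_id, env in genome_plan:
        labels[genome_id] = env
        proteome: list[ProteinRecord] = []
        serial = 0
        for fam in families:
            prevalence = (
                fam.prevalence_related
                if env is EnvironmentSet.RELATED
                else fam.prevalence_unrelated
            )
            if rng.random() >= prevalence:
                continue
            copies = int(_zt_geometric(rng, fam.mean_copies, 1)[0])
            for _ in range(copies):
                pid = f"{genome_id}_p{serial:04d}"
                serial += 1
                proteome.append(
                    ProteinRecord(
                        id=pid,
                        sequence=_mutate(
                            rng, fam.consensus, config.mutation_rate_per_site
                        ),
                        origin=Origin.GENOME,
                        genome_id=genome_id,
                        environment_set=env,
                        complete=True,
                        description=f"member of {fam.family_id}",
                    )
                )
                manifest[pid] = fam.family_id
        for _ in range(config.proteins_per_genome):
            pid = f"{genome_id}_p{serial:04d}"
            serial += 1
            proteome.append(
                ProteinRecord(
                    id=pid,
                    sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                    origin=Origin.GENOME,
                    genome_id=genome_id,
                    environment_set=env,
                    complete=True,
                    description="hypothetical protein",
                )
            )
        genomes[genome_id] = proteome

    # Metagenome: sample related-genome proteins; a fraction truncated and
    # flagged incomplete; singleton decoys are i.i.d. random sequences.
    related_pool = [
        record
        for genome_id, env in genome_plan
        if env is EnvironmentSet.RELATED
        for record in genomes[genome_id]
    ]
    metagenome: list[ProteinRecord] = []
    for i in range(config.n_metagenome_orfs):
        oid = f"ORF{i:06d}"
        if rng.random() < config.singleton_fraction:
            metagenome.append(
                ProteinRecord(
                    id=oid,
                    sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                    origin=Origin.METAGENOME,
                )
            )
            continue
        source = related_pool[int(rng.integers(len(related_pool)))]
        seq = source.sequence
        complete = True
        if rng.random() < config.incomplete_orf_fraction:
            complete = False
            cut = int(round(len(seq) * rng.uniform(0.2, 0.6)))
            cut = max(1, min(cut, len(seq) - 1))
            seq = seq[cut:] if rng.random() < 0.5 else seq[:-cut]
        metagenome.append(
            ProteinRecord(
                id=oid,
                sequence=seq,
                origin=Origin.METAGENOME,
                complete=complete,
            )
        )
        if source.id in manifest:
            manifest[oid] = manifest[source.id]

    known_seed_alignments = {
        fam.family_id: [
            _mutate(rng, fam.consensus, config.mutation_rate_per_site)
            for _ in range(config.known_seed_depth)
        ]
        for fam in families
        if fam.is_known
    }

    return World(
        config=config,
        metagenome=metagenome,
        genomes=genomes,
        labels=labels,
        families=families,
        manifest=manifest,
        known_seed_alignments=known_seed_alignments,
    )


def world_truth_counts(world: World) -> pd.DataFrame:
    """Exact per-family (g, n, G, N) from the manifest, bypassing any search.

    g/n count member proteins in related/unrelated genomes; G/N count genomes
    of each set with at least one member.
    """
    known_ids = {r.id for proteome in world.genomes.values() for r in proteome}
    fam_ids = {f.family_id for f in world.families}
    rows = {
        f.family_id: {"g": 0, "n": 0, "G": set(), "N": set()} for f in world.families
    }
    meta_ids = {r.id for r in world.metagenome}
    for member_id, family_id in world.manifest.items():
        if family_id not in fam_ids:
            raise IntegrityError(f"manifest names unknown family {family_id!r}")
        if member_id in meta_ids:
            continue
        if member_id not in known_ids:
            raise IntegrityError(f"manifest member {member_id!r} not in any proteome")
        genome_id = member_id.split("_p")[0]
        env = world.labels[genome_id]
        row = rows[family_id]
        if env is EnvironmentSet.RELATED:
            row["g"] += 1
            row["G"].add(genome_id)
        else:
            row["n"] += 1
            row["N"].add(genome_id)
    table = pd.DataFrame(
        [
            {
                "family_id": fid,
                "g": row["g"],
                "n": row["n"],
                "G": len(row["G"]),
                "N": len(row["N"]),
            }
            for fid, row in rows.items()
        ]
    ).set_index("family_id")
    return table


def dataset_totals(world: World) -> dict[str, int]:
    """(g_T, n_T, G_T, N_T) of the generated genome collections."""
    g_T = sum(
        len(p)
        for gid, p in world.genomes.items()
        if world.labels[gid] is EnvironmentSet.RELATED
    )
    n_T = sum(
        len(p)
        for gid, p in world.genomes.items()
        if world.labels[gid] is EnvironmentSet.UNRELATED
    )
    return {
        "g_T": g_T,
        "n_T": n_T,
        "G_T": world.config.n_related_genomes,
        "N_T": world.config.n_unrelated_genomes,
    }


def write_world(world: World, out_dir: str | Path) -> None:
    """Write the world as FASTA/TSV files (metagenome, per-genome proteomes,
    label TSV, truth manifest, known-family seed alignments)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(world.metagenome, out / "metagenome.faa")
    genome_dir = out / "genomes"
    genome_dir.mkdir(exist_ok=True)
    for genome_id, proteome in world.genomes.items():
        write_fasta(proteome, genome_dir / f"{genome_id}.faa")
    with open(out / "labels.tsv", "w") as handle:
        for genome_id, env in world.labels.items():
            handle.write(f"{genome_id}\t{env.value}\n")
    with open(out / "truth_manifest.tsv", "w") as handle:
        for member_id, family_id in sorted(world.manifest.items()):
            handle.write(f"{member_id}\t{family_id}\n")
    seed_dir = out / "known_seeds"
    seed_dir.mkdir(exist_ok=True)
    for family_id, rows in world.known_seed_alignments.items():
        with open(seed_dir / f"{family_id}.afa", "w") as handle:
            for i, row in enumerate(rows):
                handle.write(f">{family_id}_seed{i}\n{row}\n")
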