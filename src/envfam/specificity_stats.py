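"""Environment-specificity statistics for protein families.

For each family, occurrences are counted in two labelled genome collections:
an environment-related set and an unrelated control set.  With

* ``g`` / ``n`` — number of family member proteins found in the related /
  unrelated genomes (one best hit per protein),
* ``G`` / ``N`` — number of related / unrelated genomes with at least one
  member,
* ``g_T, n_T`` — total proteins in each collection, and
* ``G_T, N_T`` — number of genomes in each collection,

three statistics summarise how specific a family is to the environment:

* overrepresentation  ``Ov = (g / g_T) / ((n + 1) / n_T)`` — relative
  per-protein abundance, with a +1 pseudocount shielding the control
  denominator;
* expansion  ``Ex = g / (G + 1) - n / (N + 1)`` — excess per-genome copy
  number, highlighting families that are multiplied within carrier genomes;
* essentiality  ``Es = G / G_T - N / N_T`` in [-1, 1] — difference between
  the fractions of genomes carrying the family; ``Es = 1`` means every
  related genome carries it and no control genome does.

Computations run in full precision; table output rounds half-up to 2
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LabelError
from .profile_models import ProfileModel, scan
from .sequence_io import EnvironmentSet, ProteinRecord


@dataclass(frozen=True)
class DatasetTotals:
    """Collection-wide totals; defaults are the human-gut study scale."""

    g_T: int = 224_099
    n_T: int = 1_423_331
    G_T: int = 65
    N_T: int = 493

    def __post_init__(self) -> None:
        if min(self.g_T, self.n_T, self.G_T, self.N_T) <= 0:
            raise ValueError("all totals must be positive")


@dataclass(frozen=True)
class FamilyCounts:
    family_id: str
    g: int
    n: int
    G: int
    N: int

    def __post_init__(self) -> None:
        if min(self.g, self.n, self.G, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.G > self.g or self.N > self.n:
            raise ValueError("genome counts cannot exceed occurrence counts")


def round_half_up(value: float, digits: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_ov(g: int, n: int, totals: DatasetTotals) -> float:
    """Comparative overrepresentation; 0 when the family is absent (g=0)."""
    return (g / totals.g_T) / ((n + 1) / totals.n_T)


def compute_ex(g: int, n: int, G: int, N: int) -> float:
    """Expansion (per-genome copy-number excess); may be negative."""
    return g / (G + 1) - n / (N + 1)


def compute_es(G: int, N: int, totals: DatasetTotals) -> float:
    """Essentiality in [-1, 1]."""
    if G > totals.G_T or N > totals.N_T:
        raise ValueError("G/N cannot exceed the genome totals")
    return G / totals.G_T - N / totals.N_T


def score_table(counts: pd.DataFrame, totals: DatasetTotals) -> pd.DataFrame:
    """Ov/Ex/Es per row of a (g, n, G, N) counts table, full precision."""
    out = counts.copy()
    out["ov"] = (counts["g"] / totals.g_T) / ((counts["n"] + 1) / totals.n_T)
    out["ex"] = counts["g"] / (counts["G"] + 1) - counts["n"] / (counts["N"] + 1)
    out["es"] = counts["G"] / totals.G_T - counts["N"] / totals.N_T
    return out


def format_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Published-table form: statistics rounded half-up to 2 decimals."""
    out = scores.copy()
    for col in ("ov", "ex", "es"):
        out[col] = out[col].map(lambda v: round_half_up(v, 2))
    return out


# ---------------------------------------------------------------------------
# Counting hits in the genome collections
# ---------------------------------------------------------------------------

def count_hits(
    family_models: Sequence[ProfileModel],
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    labels: Mapping[str, EnvironmentSet],
    max_evalue: float = 1e-4,
) -> pd.DataFrame:
    """(g, n, G, N) per family model against labelled proteomes.

    One best hit per protein: a protein counts once per model regardless of
    how many domain copies it carries.
    """
    for genome_id in proteomes:
        if genome_id not in labels:
            raise LabelError(f"genome {genome_id!r} has no environment label")
    rows = []
    for model in family_models:
        g = n = 0
        G: set[str] = set()
        N: set[str] = set()
        for genome_id, proteome in proteomes.items():
            hits = scan(model, list(proteome), max_evalue=max_evalue)
            if not hits:
                continue
            if labels[genome_id] is EnvironmentSet.RELATED:
                g += len(hits)
                G.add(genome_id)
            else:
                n += len(hits)
                N.add(genome_id)
        rows.append(
            {"family_id": model.model_id, "g": g, "n": n, "G": len(G), "N": len(N)}
        )
    return pd.DataFrame(rows).set_index("family_id")


# ---------------------------------------------------------------------------
# Rankings and figure-style reports
# ---------------------------------------------------------------------------

def rank_families(
    scores: pd.DataFrame, by: str = "es", top_k: int | None = None
) -> pd.DataFrame:
    """Stable descending sort on one statistic, ties broken by family id."""
    if by not in ("ov", "ex", "es"):
        raise ValueError(f"unknown ranking statistic {by!r}")
    table = scores if "family_id" in scores.columns else scores.reset_index()
    ranked = table.sort_values(
        by=[by, "family_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    if top_k is not None:
        ranked = ranked.head(top_k)
    return ranked


def coverage_report(
    proteins: Sequence[ProteinRecord],
    known_hit_ids: set[str],
    new_family_hit_ids: set[str],
    microfamily_ids: set[str] | None = None,
) -> dict[str, float]:
    """Fraction of proteins covered by known families, gained by new
    families, left in microfamilies, or unassigned.  Fractions sum to 1."""
    total = len(proteins)
    if total == 0:
        return {"known": 0.0, "new": 0.0, "microfamily": 0.0, "unassigned": 1.0}
    microfamily_ids = microfamily_ids or set()
    known = new = micro = none = 0
    for record in proteins:
        if record.id in known_hit_ids:
            known += 1
        elif record.id in new_family_hit_ids:
            new += 1
        elif record.id in microfamily_ids:
            micro += 1
        else:
            none += 1
    return {
        "known": known / total,
        "new": new / total,
        "microfamily": micro / total,
        "unassigned": none / total,
    }


def es_histogram(
    scores: pd.DataFrame, bin_width: float = 0.1
) -> pd.DataFrame:
    """Counts of families per Es bin over [-1, 1]; conserves family number."""
    n_bins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    if scores.empty:
        counts = np.zeros(n_bins, dtype=int)
    else:
        counts, _ = np.histogram(scores["es"].to_numpy(), bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    format_scores(scores).to_csv(path, sep="\t", index=True, float_format="%.2f")


def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"family_id", "g", "n", "G", "N"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    return table.set_index("family_id")
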