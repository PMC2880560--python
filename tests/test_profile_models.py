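import math

import numpy as np
import pytest

from envfam.errors import CalibrationError, FamilyCollapseError, UncalibratedModelError
from envfam.profile_models import (
    ProfileHit,
    build_profile,
    calibrate,
    iterate_profile,
    merge_overlapping_clusters,
    scan,
    score_sequence,
)
from envfam.sequence_io import AMINO_ACIDS, Interval, ProteinRecord
from envfam.synthetic_data import WorldConfig, generate_world


def _mutants(rng, consensus, n, rate=0.15):
    out = []
    for k in range(n):
        seq = list(consensus)
        for pos in np.flatnonzero(rng.random(len(seq)) < rate):
            seq[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
        out.append("".join(seq))
    return out


@pytest.fixture(scope="module")
def family_model():
    rng = np.random.default_rng(4)
    consensus = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=120))
    members = _mutants(rng, consensus, 12)
    model = calibrate(build_profile(members, "fam"), seed=99)
    records = [ProteinRecord(id=f"m{i:02d}", sequence=s) for i, s in enumerate(members)]
    return model, records, consensus


class TestBuildProfile:
    def test_identical_rows_maximal_consensus_score(self):
        rows = ["MKVLAT"] * 5
        model = build_profile(rows, "toy")
        for pos, residue in enumerate("MKVLAT"):
            column = model.scores[pos]
            assert column[AMINO_ACIDS.index(residue)] == column.max()

    def test_single_column_pseudocount_arithmetic(self):
        # 4 observations of A with alpha=0.5: p = 4.5/14; half-bit log-odds
        model = build_profile(["AG", "AG", "AG", "AG"], "col", max_gap_fraction=1.0)
        p = (4 + 0.5) / (4 + 20 * 0.5)
        expected = 2.0 * math.log2(p / 0.05)
        assert model.scores[0, AMINO_ACIDS.index("A")] == pytest.approx(expected)

    def test_uniform_column_scores_shrink_with_depth(self):
        rows_shallow = [aa + "A" for aa in AMINO_ACIDS]
        rows_deep = rows_shallow * 20
        shallow = build_profile(rows_shallow, "s", max_gap_fraction=1.0)
        deep = build_profile(rows_deep, "d", max_gap_fraction=1.0)
        # uniform usage: scores approach 0 as depth grows (p -> q)
        assert np.abs(deep.scores[0]).max() <= np.abs(shallow.scores[0]).max() + 1e-9
        assert np.abs(deep.scores[0]).max() < 0.2

    def test_gap_dominated_columns_dropped(self):
        rows = ["A-CDE", "A-CDE", "A--DE", "AKCDE"]
        model = build_profile(rows, "g")
        # column 1 has 3/4 gaps (> 50%): dropped; column 2 kept (1/4)
        assert model.length == 4

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], "none")


class TestCalibration:
    def test_evalue_at_mu_is_63_percent_of_z(self, family_model):
        model, _, _ = family_model
        assert model.evalue(model.gumbel_mu) == pytest.approx(
            (1 - math.exp(-1)) * model.z_constant, rel=1e-6
        )

    def test_doubling_z_doubles_evalues(self, family_model):
        import dataclasses

        model, _, _ = family_model
        doubled = dataclasses.replace(model, z_constant=2 * model.z_constant)
        for score in (50.0, 150.0, 400.0):
            assert doubled.evalue(score) == pytest.approx(2 * model.evalue(score))

    def test_decoys_do_not_pass_reporting_cutoff(self, family_model):
        model, _, _ = family_model
        rng = np.random.default_rng(123)
        decoys = [
            ProteinRecord(
                id=f"d{i}",
                sequence="".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 350)),
            )
            for i in range(200)
        ]
        hits = scan(model, decoys, max_evalue=1e-4)
        assert hits == []

    def test_calibration_counts_consistent(self, family_model):
        """Observed decoy counts at loose E-value thresholds stay within 3x
        of the Gumbel expectation."""
        model, _, _ = family_model
        rng = np.random.default_rng(77)
        n_decoys = 300
        scores = []
        for _ in range(n_decoys):
            seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 350))
            scores.append(score_sequence(model, seq))
        for e in (0.1, 1.0):
            threshold = model.score_threshold(e)
            observed = sum(1 for s in scores if s >= threshold)
            expected = n_decoys * e / model.z_constant
            assert observed <= 3 * max(expected, 1.0)

    def test_scan_requires_calibration(self):
        model = build_profile(["MKVLATGEWQ"] * 3, "raw")
        with pytest.raises(UncalibratedModelError):
            scan(model, [ProteinRecord(id="x", sequence="MKVLATGEWQ")])


class TestScan:
    def test_self_recovery(self, family_model):
        model, records, _ = family_model
        hits = scan(model, records, max_evalue=1e-4)
        assert {h.seq_id for h in hits} == {r.id for r in records}

    def test_hit_spans_within_bounds(self, family_model):
        model, records, _ = family_model
        for hit in scan(model, records, max_evalue=1e-4):
            record = next(r for r in records if r.id == hit.seq_id)
            assert 0 <= hit.span.start < hit.span.end <= len(record.sequence)
            m0, m1 = hit.model_span
            assert 0 <= m0 < m1 <= model.length

    def test_sorted_by_evalue(self, family_model):
        model, records, _ = family_model
        hits = scan(model, records, max_evalue=1.0)
        evalues = [h.evalue for h in hits]
        assert evalues == sorted(evalues)


class TestIterateProfile:
    def test_fixed_point_when_database_is_seed(self, family_model):
        _, records, _ = family_model
        model, members, alignment = iterate_profile(
            records, database=records, model_id="fx", iterations=5, seed=5
        )
        assert members == {r.id for r in records}
        assert len(alignment) == len(records)

    def test_planted_family_recovered_from_database(self):
        rng = np.random.default_rng(21)
        consensus = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=130))
        all_members = [
            ProteinRecord(id=f"fam{i:02d}", sequence=s)
            for i, s in enumerate(_mutants(rng, consensus, 20))
        ]
        decoys = [
            ProteinRecord(
                id=f"bg{i:02d}",
                sequence="".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 130)),
            )
            for i in range(40)
        ]
        seed_members = all_members[:4]
        database = all_members + decoys
        model, members, _ = iterate_profile(
            seed_members, database, model_id="plant", iterations=5, seed=10
        )
        planted = {r.id for r in all_members}
        assert len(members & planted) >= 0.9 * len(planted)
        assert not members & {d.id for d in decoys}

    def test_membership_monotone(self, family_model):
        _, records, _ = family_model
        # run with increasing iteration budgets; membership never shrinks
        prev: set[str] = set()
        for rounds in (1, 2, 3):
            _, members, _ = iterate_profile(
                records[:3], database=records, model_id="mono",
                iterations=rounds, seed=2,
            )
            assert prev <= members
            prev = members

    def test_collapse_raises(self):
        with pytest.raises(FamilyCollapseError):
            iterate_profile(
                [ProteinRecord(id="a", sequence="MKV")],
                database=[],
                model_id="tiny",
                min_model_length=10,
            )


class TestMergeOverlap:
    def _hit(self, model, seq, start, end):
        return ProfileHit(
            model_id=model, seq_id=seq, score=100.0, evalue=1e-9,
            span=Interval(seq, start, end, model),
        )

    def test_identical_clusters_merge(self):
        clusters = {"c1": {"s1", "s2"}, "c2": {"s1", "s2"}}
        hits = {
            "c1": [self._hit("c1", "s1", 0, 50), self._hit("c1", "s2", 0, 50)],
            "c2": [self._hit("c2", "s1", 0, 50), self._hit("c2", "s2", 0, 50)],
        }
        merged = merge_overlapping_clusters(clusters, hits)
        assert len(merged) == 1
        assert merged[0][0] == frozenset({"s1", "s2"})

    def test_disjoint_hit_sets_unchanged(self):
        clusters = {"c1": {"s1", "s2"}, "c2": {"s3", "s4"}}
        hits = {
            "c1": [self._hit("c1", "s1", 0, 50), self._hit("c1", "s2", 0, 50)],
            "c2": [self._hit("c2", "s3", 0, 50), self._hit("c2", "s4", 0, 50)],
        }
        assert len(merge_overlapping_clusters(clusters, hits)) == 2

    def test_transitive_chain_merges(self):
        clusters = {"a": {"s1", "s2"}, "b": {"s2", "s3"}, "c": {"s3", "s4"}}
        hits = {
            "a": [self._hit("a", "s1", 0, 40), self._hit("a", "s2", 0, 40)],
            "b": [self._hit("b", "s1", 0, 40), self._hit("b", "s2", 0, 40),
                  self._hit("b", "s3", 0, 40), self._hit("b", "s4", 0, 40)],
            "c": [self._hit("c", "s3", 0, 40), self._hit("c", "s4", 0, 40)],
        }
        merged = merge_overlapping_clusters(clusters, hits)
        assert len(merged) == 1
        assert merged[0][1] == frozenset({"a", "b", "c"})

    def test_insufficient_span_overlap_does_not_merge(self):
        clusters = {"c1": {"s1", "s2"}, "c2": {"s1", "s2"}}
        hits = {
            "c1": [self._hit("c1", "s1", 0, 40), self._hit("c1", "s2", 0, 40)],
            "c2": [self._hit("c2", "s1", 60, 100), self._hit("c2", "s2", 60, 100)],
        }
        assert len(merge_overlapping_clusters(clusters, hits)) == 2

    def test_idempotent_on_own_output(self):
        clusters = {"a": {"s1", "s2"}, "b": {"s2", "s3"}}
        hits = {
            "a": [self._hit("a", "s1", 0, 40), self._hit("a", "s2", 0, 40),
                  self._hit("a", "s3", 0, 40)],
            "b": [self._hit("b", "s1", 0, 40), self._hit("b", "s2", 0, 40),
                  self._hit("b", "s3", 0, 40)],
        }
        merged = merge_overlapping_clusters(clusters, hits)
        again = merge_overlapping_clusters(
            {"m0": set(merged[0][0])}, {"m0": hits["a"]}
        )
        assert len(again) == 1 and again[0][0] == merged[0][0]
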