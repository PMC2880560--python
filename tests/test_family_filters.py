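import numpy as np
import pytest

from envfam.family_discovery import Family, FamilyCategory
from envfam.family_filters import (
    curation_flags,
    drop_known_overlap,
    low_complexity_fraction,
    require_genomic_coverage,
    require_min_metagenome_hits,
    require_model_length,
)
from envfam.profile_models import ProfileHit, build_profile, calibrate
from envfam.sequence_io import AMINO_ACIDS, Interval, ProteinRecord


def _hit(model, seq, start, end):
    return ProfileHit(
        model_id=model, seq_id=seq, score=200.0, evalue=1e-20,
        span=Interval(seq, start, end, model),
    )


def _family(family_id, members, model_rows=None, length=120):
    rng = np.random.default_rng(abs(hash(family_id)) % 2**31)
    rows = model_rows or [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    ] * 3
    model = calibrate(
        build_profile(rows, model_id=family_id), decoy_count=60, seed=1
    )
    return Family(
        family_id=family_id,
        category=FamilyCategory.NOVEL,
        members=members,
        model=model,
        alignment=rows,
    )


class TestKnownOverlapBoundary:
    def _family_with_overlap(self, n_members, n_overlapping):
        members = [_hit("f", f"s{i}", 10, 110) for i in range(n_members)]
        family = _family("f", members)
        intervals = [
            Interval(f"s{i}", 50, 90, "KNOWN1") for i in range(n_overlapping)
        ]
        return family, intervals

    def test_thirty_percent_removed(self):
        family, intervals = self._family_with_overlap(10, 3)
        kept, report = drop_known_overlap([family], intervals, max_frac=0.20)
        assert kept == [] and report.removed

    def test_exactly_twenty_percent_kept(self):
        # "more than 20%" is strict: 2/10 stays
        family, intervals = self._family_with_overlap(10, 2)
        kept, report = drop_known_overlap([family], intervals, max_frac=0.20)
        assert kept == [family] and not report.removed

    def test_matches_brute_force_overlap_count(self):
        rng = np.random.default_rng(8)
        members = [_hit("f", f"s{i}", 0, 100) for i in range(20)]
        family = _family("f", members)
        intervals = []
        overlapping = set()
        for i in range(20):
            if rng.random() < 0.5:
                start = int(rng.integers(0, 150))
                iv = Interval(f"s{i}", start, start + 30, "KNOWN1")
                intervals.append(iv)
                if start < 100:  # touches the member span [0, 100)
                    overlapping.add(i)
        kept, _ = drop_known_overlap([family], intervals, max_frac=0.20)
        expected_removed = len(overlapping) / 20 > 0.20
        assert (kept == []) == expected_removed


class TestGenomicCoverageBoundary:
    def _setup(self, protein_len):
        rng = np.random.default_rng(5)
        core = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=80))
        family = _family("f", [_hit("f", "orf0", 0, 80)], model_rows=[core] * 4)
        pad = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=protein_len - 80))
        protein = ProteinRecord(id="gp0", sequence=core + pad, genome_id="g1")
        return family, {"g1": [protein]}

    def test_80_percent_coverage_kept(self):
        family, proteomes = self._setup(100)
        kept, _ = require_genomic_coverage([family], proteomes, min_frac=0.75)
        assert kept == [family]

    def test_74_percent_coverage_removed(self):
        family, proteomes = self._setup(108)  # 80/108 = 0.74
        kept, report = require_genomic_coverage([family], proteomes, min_frac=0.75)
        assert kept == [] and report.removed


class TestModelLengthBoundary:
    @pytest.mark.parametrize("length,kept", [(100, True), (99, False), (150, True)])
    def test_inclusive_at_100(self, length, kept):
        family = _family(f"len{length}", [_hit("m", "s0", 0, 50)], length=length)
        survivors, report = require_model_length([family], min_len=100)
        assert bool(survivors) == kept
        assert report.families_in == 1
        assert report.families_out == int(kept)


class TestMinHitsBoundary:
    def _world(self, n_hits):
        rng = np.random.default_rng(6)
        consensus = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=110))
        rows = []
        for _ in range(4):
            seq = list(consensus)
            for pos in np.flatnonzero(rng.random(110) < 0.1):
                seq[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
            rows.append("".join(seq))
        family = _family("f", [], model_rows=rows)
        metagenome = []
        for i in range(n_hits):
            seq = list(consensus)
            for pos in np.flatnonzero(rng.random(110) < 0.1):
                seq[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
            metagenome.append(ProteinRecord(id=f"orf{i}", sequence="".join(seq)))
        return family, metagenome

    @pytest.mark.parametrize("n_hits,kept", [(10, True), (9, False)])
    def test_inclusive_at_10(self, n_hits, kept):
        family, metagenome = self._world(n_hits)
        survivors, _ = require_min_metagenome_hits(
            [family], metagenome, min_hits=10
        )
        assert bool(survivors) == kept


class TestFilterReports:
    def test_report_bookkeeping(self):
        families = [
            _family(f"f{i}", [_hit(f"f{i}", "s0", 0, 50)], length=80 + 40 * i)
            for i in range(3)
        ]  # lengths 80, 120, 160
        survivors, report = require_model_length(families, min_len=100)
        assert report.families_in == 3
        assert report.families_out == 2
        assert report.families_out == report.families_in - len(report.removed)
        assert set(report.removed) == {"f0"}

    def test_independent_filters_commute(self):
        rng = np.random.default_rng(11)
        families = []
        metagenomes = {}
        pool = []
        for i in range(4):
            family, metagenome = TestMinHitsBoundary()._world(8 + i)
            family = _family(f"c{i}", family.members, length=90 + 10 * i)
            families.append(family)
            pool.extend(metagenome)
        a1, _ = require_model_length(families, min_len=100)
        a2, _ = require_min_metagenome_hits(a1, pool, min_hits=10)
        b1, _ = require_min_metagenome_hits(families, pool, min_hits=10)
        b2, _ = require_model_length(b1, min_len=100)
        assert {f.family_id for f in a2} == {f.family_id for f in b2}


class TestCurationFlags:
    def test_identical_members_no_flags(self):
        rng = np.random.default_rng(2)
        row = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=100))
        family = _family("id", [_hit("id", "s0", 0, 100)], model_rows=[row] * 6)
        flags = curation_flags(family)
        assert not flags["divergent"] and not flags["no_core"]

    def test_random_members_divergent(self):
        rng = np.random.default_rng(3)
        rows = [
            "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=100))
            for _ in range(12)
        ]
        family = _family("div", [], model_rows=rows)
        flags = curation_flags(family)
        assert flags["divergent"]

    def test_low_complexity_detection(self):
        assert low_complexity_fraction("A" * 50) == 1.0
        rng = np.random.default_rng(4)
        random_seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=50))
        assert low_complexity_fraction(random_seq) < 0.3

    def test_reference_hit_boundary_at_15(self):
        rng = np.random.default_rng(9)
        consensus = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=110))
        family = _family("ref", [], model_rows=[consensus] * 4)

        def reference(n):
            return [
                ProteinRecord(id=f"nr{i}", sequence=consensus) for i in range(n)
            ]

        assert curation_flags(family, reference_db=reference(14))["few_reference_hits"]
        assert not curation_flags(family, reference_db=reference(15))[
            "few_reference_hits"
        ]

    def test_no_core_flag(self):
        # members split over disjoint model regions leave no common core
        left = "ACDEFGHIKL" * 5 + "-" * 50
        right = "-" * 50 + "MNPQRSTVWY" * 5
        family = _family("split", [], model_rows=["ACDEFGHIKL" * 10] * 3)
        family.alignment = [left, left, right, right, right]
        # max column coverage 3/5 >= 50% of members: not flagged
        assert not curation_flags(family)["no_core"]
        quarters = [
            "-" * (25 * i) + "ACDEF" * 5 + "-" * (75 - 25 * i) for i in range(4)
        ]
        family.alignment = quarters
        # every column covered by only 1 of 4 members (< 50%): flagged
        assert curation_flags(family)["no_core"]

    def test_annotatable_flag(self):
        family = _family("ann", [_hit("ann", f"s{i}", 0, 50) for i in range(4)])
        descriptions = {f"s{i}": "putative ABC transporter" for i in range(4)}
        assert curation_flags(family, member_descriptions=descriptions)["annotatable"]
        vague = {f"s{i}": "hypothetical protein" for i in range(4)}
        assert not curation_flags(family, member_descriptions=vague)["annotatable"]
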