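"""Satellite detection: seeds, delimitation, similarity, filtering."""

import math

import numpy as np
import pytest

from satscribe._seq import rotate
from satscribe.detection import (
    delimit_satellite,
    detect_satellites,
    filter_satellites,
    find_seed_clusters,
    is_primitive_kmer,
    merge_seed_clusters,
    repeat_similarity,
)
from satscribe.records import SatelliteRecord
from satscribe.simulate import PlantedSatelliteSpec, random_unit, simulate_genome

from oracles import census_regions, mean_pairwise_identity, primitive_brute


class TestPrimitiveKmer:
    @pytest.mark.parametrize(
        "kmer,expected",
        [
            ("ACACACACAC", False),  # period 2 tiles the decamer
            ("AAAAAAAAAA", False),  # period 1
            ("ACGTAACGTA", False),  # period 5
            ("ACGTACGTTG", True),   # no tiling period
            ("ACACACACAT", True),   # near-tandem but not exact
        ],
    )
    def test_examples(self, kmer, expected):
        assert is_primitive_kmer(kmer) is expected

    def test_agrees_with_brute_force_on_random_decamers(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            kmer = "".join(rng.choice(bases, size=10))
            assert is_primitive_kmer(kmer) == primitive_brute(kmer)
        # and on constructed tandems of unit length 1, 2, 5
        for p in (1, 2, 5):
            unit = "".join(rng.choice(bases, size=p))
            assert is_primitive_kmer(unit * (10 // p)) == primitive_brute(unit * (10 // p))

    @pytest.mark.parametrize("bad", ["ACGT", "ACGTACGTACGT", "ACGTACGTAN"])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            is_primitive_kmer(bad)


class TestSeedClusters:
    def test_random_genome_has_no_clusters(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=10_000))
        assert census_regions(seq) == set()  # oracle confirms the premise
        assert find_seed_clusters("c", seq) == []

    def test_planted_unit_produces_one_candidate_region(self):
        rng = np.random.default_rng(3)
        unit = random_unit(rng, 40)
        bg = "".join(rng.choice(np.array(list("ACGT")), size=10_000))
        seq = bg[:2000] + unit * 5 + bg[2000:]
        regions = merge_seed_clusters(find_seed_clusters("c", seq))
        assert len(regions) == 1
        # the candidate covers the planted array (chance off-array seed
        # occurrences may widen it; delimitation trims those)
        assert regions[0].start <= 2000
        assert regions[0].end >= 2190
        assert regions[0].end - regions[0].start < 800

    def test_unit_too_long_for_window_is_not_clustered(self):
        # decamers of a 270-mer unit recur every 270 nt: four occurrences
        # span 3*270+10 = 820 nt > the 800-nt window, so no seed cluster
        # (unit verified by exhaustive census to repeat no decamer internally)
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(np.array(list("ACGT")), size=270))
        bg = "".join(rng.choice(np.array(list("ACGT")), size=4000))
        seq = bg[:1500] + unit * 4 + bg[1500:]
        assert census_regions(seq) == set()
        assert find_seed_clusters("c", seq) == []

    def test_unit_above_200_rejected_at_delimitation(self):
        # a 250-mer can still seed (occurrence span 760 nt < 800) but the
        # inferred unit is outside [10, 200] and no satellite is reported
        rng = np.random.default_rng(6)
        unit = "".join(rng.choice(np.array(list("ACGT")), size=250))
        bg = "".join(rng.choice(np.array(list("ACGT")), size=4000))
        seq = bg[:1500] + unit * 4 + bg[1500:]
        assert detect_satellites({"c": seq}) == []

    def test_matches_exhaustive_census_on_planted_genomes(self):
        # several planted arrays in <= 50 kb, implementation vs brute force
        rng = np.random.default_rng(11)
        specs = [
            PlantedSatelliteSpec("c", 2000, random_unit(rng, 25), 8),
            PlantedSatelliteSpec("c", 9000, random_unit(rng, 61), 5),
            PlantedSatelliteSpec("c", 20000, random_unit(rng, 120), 4),
        ]
        genome, _, _ = simulate_genome(specs, 30_000, seed=12)
        seq = genome["c"]
        got = {
            (r.start, r.end) for r in merge_seed_clusters(find_seed_clusters("c", seq))
        }
        assert got == census_regions(seq)

    def test_monotonic_in_min_copies_and_window(self, small_scene):
        seq = small_scene.genome["chrI"]

        def n_sats(min_copies, window):
            return len(
                detect_satellites({"chrI": seq}, min_copies=min_copies, window_nt=window)
            )

        base = n_sats(4, 800)
        assert n_sats(6, 800) <= base   # stricter copy requirement
        assert n_sats(4, 400) <= base   # narrower window


class TestDelimitation:
    def test_perfect_array_recovered_exactly(self, planted_perfect):
        genome, truth = planted_perfect
        [rec] = detect_satellites(genome)
        t = truth.satellites[0]
        assert (rec.start, rec.end) == (t.start, t.end)
        assert rec.repeat_length == 45
        assert rec.n_repeats == 6
        assert rec.similarity == 1.0
        assert rec.same_length_frac == 1.0

    def test_xsat_geometry_with_truncated_last_copy(self):
        # long unique satellite: 134 repeats of 45 nt, total 6016 nt
        rng = np.random.default_rng(8)
        unit = random_unit(rng, 45)
        spec = PlantedSatelliteSpec("X", 3000, unit, 134, truncate_to=6016)
        genome, _, truth = simulate_genome([spec], 15_000, seed=9)
        [rec] = detect_satellites(genome)
        assert rec.length_nt == 6016
        assert rec.repeat_length == 45
        assert rec.n_repeats == 134
        assert rec.start == truth.satellites[0].start

    def test_noisy_array_boundaries_within_one_unit(self):
        rng = np.random.default_rng(7)
        unit = random_unit(rng, 45)
        spec = PlantedSatelliteSpec("c", 2000, unit, 10, substitution_rate=0.05)
        genome, _, truth = simulate_genome([spec], 10_000, seed=7)
        [rec] = detect_satellites(genome)
        t = truth.satellites[0]
        assert abs(rec.start - t.start) <= 45
        assert abs(rec.end - t.end) <= 45
        assert rec.n_repeats == t.n_copies
        assert rec.repeat_length == 45

    def test_recovery_rate_under_noise(self):
        # >= 95% of planted arrays (5% substitutions, >= 8 copies) recovered
        # with the exact unit length
        hits = 0
        n = 100
        for rep in range(n):
            rng = np.random.default_rng(10_000 + rep)
            unit = random_unit(rng, int(rng.integers(15, 80)))
            spec = PlantedSatelliteSpec(
                "c", 2000, unit, int(rng.integers(8, 20)), substitution_rate=0.05
            )
            genome, _, _ = simulate_genome([spec], 8_000, seed=20_000 + rep)
            recs = detect_satellites(genome)
            if len(recs) == 1 and recs[0].repeat_length == len(unit):
                hits += 1
        assert hits >= 95


class TestSimilarity:
    def test_identical_copies_score_one(self):
        assert repeat_similarity(["ACGTACGTAC"] * 5, 10) == 1.0

    def test_single_mismatch_pair(self):
        assert repeat_similarity(["ACGTACGTAC", "ACGTACGTAT"], 10) == pytest.approx(0.9)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        unit = random_unit(rng, 45)
        copies = []
        for _ in range(10):
            c = list(unit)
            for i in np.nonzero(rng.random(45) < 0.05)[0]:
                c[i] = "ACGT"[rng.integers(4)]
            copies.append("".join(c))
        assert repeat_similarity(copies, 45) == pytest.approx(
            mean_pairwise_identity(copies)
        )

    def test_undefined_below_two_same_length_copies(self):
        assert math.isnan(repeat_similarity(["ACGTACGTAC", "ACGTACGT"], 10))


class TestFilter:
    def _rec(self, n, n_modal, unit=20):
        copies = [("A" * (unit - 1) + "C")] * n_modal + ["A" * (unit + 3)] * (n - n_modal)
        return SatelliteRecord(
            chrom="c",
            start=0,
            end=sum(len(c) for c in copies),
            repeat_length=unit,
            repeats=copies,
            similarity=1.0,
            same_length_frac=n_modal / n,
        )

    def test_threshold_keeps_and_drops(self):
        keep = self._rec(10, 7)   # 0.7 >= 0.6
        drop = self._rec(10, 5)   # 0.5 < 0.6
        assert filter_satellites([keep, drop]) == [keep]

    def test_output_sorted_by_position(self):
        a, b = self._rec(10, 10), self._rec(10, 10)
        b.start, b.end = 1000, 1000 + b.length_nt
        a_shift = 5000
        a.start, a.end = a_shift, a_shift + a.length_nt
        assert filter_satellites([a, b]) == [b, a]


def test_rotated_unit_detected_with_same_span(planted_perfect):
    # detection is phase-free: a rotation of the unit describes the same array
    genome, truth = planted_perfect
    [rec] = detect_satellites(genome)
    t = truth.satellites[0]
    assert rec.sequence == genome["chr1"][t.start : t.end]
    assert any(
        rotate(rec.repeats[0], r) == t.unit for r in range(45)
    )
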