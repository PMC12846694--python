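import math

import numpy as np
import pytest

from rohscan.islands_sharing import (
    IslandSegment,
    SnpIncidenceTrack,
    build_islands,
    call_hotspots,
    islands_for_population,
    shared_with_reference,
    snp_incidence,
    venn_segments,
)
from rohscan.roh_detection import RohSegment

from conftest import make_markers


def island(pop, chrom, start, end, n=5, peak=1.0):
    return IslandSegment(
        population=pop, chromosome=chrom, start_bp=start, end_bp=end,
        n_hotspot_snps=n, peak_incidence=peak,
    )


def track_from(values, positions=None):
    values = np.asarray(values, dtype=float)
    markers = make_markers(positions if positions is not None else (np.arange(len(values)) + 1) * 10_000)
    return SnpIncidenceTrack(population="pop", markers=markers, incidence=values)


class TestIncidence:
    def test_counting(self):
        markers = make_markers((np.arange(200) + 1) * 10_000)
        segs = [
            RohSegment(sample=f"i{k}", chromosome=1, start_bp=1_000_000, end_bp=1_500_000, n_snps=51)
            for k in range(9)
        ]
        track = snp_incidence(segs, markers, [f"i{k}" for k in range(10)])
        covered = (markers.positions >= 1_000_000) & (markers.positions <= 1_500_000)
        assert np.allclose(track.incidence[covered], 0.9)
        assert np.allclose(track.incidence[~covered], 0.0)

    def test_no_roh_all_zero(self):
        markers = make_markers((np.arange(50) + 1) * 10_000)
        track = snp_incidence([], markers, ["a", "b"])
        assert not track.incidence.any()

    def test_individual_counted_once_per_marker(self):
        markers = make_markers((np.arange(100) + 1) * 10_000)
        # two disjoint segments of one individual both covering different spans
        segs = [
            RohSegment(sample="a", chromosome=1, start_bp=10_000, end_bp=200_000, n_snps=20),
            RohSegment(sample="a", chromosome=1, start_bp=300_000, end_bp=500_000, n_snps=21),
        ]
        track = snp_incidence(segs, markers, ["a"])
        assert track.incidence.max() == 1.0

    def test_overlapping_segments_rejected(self):
        markers = make_markers((np.arange(100) + 1) * 10_000)
        segs = [
            RohSegment(sample="a", chromosome=1, start_bp=10_000, end_bp=200_000, n_snps=20),
            RohSegment(sample="a", chromosome=1, start_bp=150_000, end_bp=400_000, n_snps=26),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            snp_incidence(segs, markers, ["a"])

    def test_empty_population_rejected(self):
        markers = make_markers([10_000])
        with pytest.raises(ValueError, match="no individuals"):
            snp_incidence([], markers, [])


class TestHotspots:
    def test_clear_separation(self):
        values = np.full(1_000, 0.1)
        values[100:110] = 0.9
        hot = call_hotspots(track_from(values))
        assert set(hot) == set(range(100, 110))

    def test_all_tied_returns_all_with_warning(self):
        values = np.full(1_000, 0.5)
        with pytest.warns(UserWarning, match="tied"):
            hot = call_hotspots(track_from(values))
        assert len(hot) == 1_000

    def test_all_zero_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no hotspots"):
            hot = call_hotspots(track_from(np.zeros(100)))
        assert len(hot) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_and_cut_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=500)
        if values.max() == 0:
            values[0] = 0.5
        hot = set(call_hotspots(track_from(values), top_fraction=0.01))
        # oracle: threshold at the ceil(f*M)-th largest value, ties included
        k = math.ceil(0.01 * len(values))
        thr = np.sort(values)[::-1][k - 1]
        expect = {i for i, v in enumerate(values) if v >= thr and v > 0}
        assert hot == expect

    def test_count_at_least_top_fraction_of_nonzero(self, rng):
        values = rng.uniform(0, 1, 800)
        values[rng.random(800) < 0.3] = 0.0
        hot = call_hotspots(track_from(values), top_fraction=0.05)
        nonzero = int((values > 0).sum())
        assert len(hot) >= math.ceil(0.05 * nonzero)
        assert all(values[i] > 0 for i in hot)


class TestIslands:
    def test_adjacent_hotspots_merge(self):
        markers = make_markers([1_000_000, 1_100_000, 1_200_000, 5_000_000], chromosomes=[8] * 4)
        islands = build_islands(np.array([0, 1, 2]), markers, population="p")
        assert len(islands) == 1
        assert (islands[0].start_bp, islands[0].end_bp) == (1_000_000, 1_200_000)
        assert islands[0].chromosome == 8

    def test_large_gap_splits_islands(self):
        markers = make_markers([1_000_000, 1_800_000])
        islands = build_islands(np.array([0, 1]), markers)
        assert len(islands) == 2

    def test_isolated_hotspot_zero_span_retained(self):
        markers = make_markers([1_000_000, 5_000_000])
        islands = build_islands(np.array([0]), markers)
        assert len(islands) == 1
        assert islands[0].start_bp == islands[0].end_bp == 1_000_000

    def test_non_adjacent_map_indices_split(self):
        # markers 0 and 2 are hotspots but marker 1 between them is not
        markers = make_markers([1_000_000, 1_050_000, 1_100_000])
        islands = build_islands(np.array([0, 2]), markers)
        assert len(islands) == 2

    def test_islands_disjoint_and_cover_hotspots(self, rng):
        markers = make_markers(np.cumsum(rng.integers(10_000, 200_000, 300)))
        hot = np.flatnonzero(rng.random(300) < 0.2)
        islands = build_islands(hot, markers)
        assert sum(i.n_hotspot_snps for i in islands) == len(hot)
        spans = sorted((i.start_bp, i.end_bp) for i in islands)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestVenn:
    def test_pairwise_overlap(self):
        counts = venn_segments(
            {
                "A": [island("A", 1, 1_000_000, 2_000_000)],
                "B": [island("B", 1, 1_500_000, 2_500_000)],
                "C": [],
            }
        )
        assert counts.diagram["AB"] == 1
        assert counts.diagram["ABC"] == 0
        assert counts.diagram["only_A"] == 0

    def test_identical_lists_all_triple(self):
        isl = [island("x", 1, 1_000_000, 2_000_000), island("x", 2, 5_000_000, 6_000_000)]
        counts = venn_segments({"A": isl, "B": isl, "C": isl})
        assert counts.diagram["ABC"] == 2
        assert counts.diagram["only_A"] == counts.diagram["AB"] == 0

    def test_disjoint_lists(self):
        counts = venn_segments(
            {
                "A": [island("A", 1, 1, 10)],
                "B": [island("B", 2, 1, 10), island("B", 2, 100, 200)],
                "C": [island("C", 3, 1, 10)],
            }
        )
        assert counts.diagram["only_A"] == 1
        assert counts.diagram["only_B"] == 2
        assert counts.diagram["only_C"] == 1

    def test_conservation_each_group_partitions(self, rng):
        def random_islands(pop, n):
            return [
                island(pop, int(rng.integers(1, 3)), s, s + int(rng.integers(1, 500_000)))
                for s in rng.integers(1, 50_000_000, n)
            ]

        groups = {p: random_islands(p, 12) for p in ("A", "B", "C")}
        counts = venn_segments(groups)
        for pop, regions in counts.regions_by_group.items():
            assert sum(regions.values()) == len(groups[pop])

    def test_single_bp_overlap_counts(self):
        counts = venn_segments(
            {
                "A": [island("A", 1, 1_000_000, 2_000_000)],
                "B": [island("B", 1, 2_000_000, 3_000_000)],
                "C": [],
            }
        )
        assert counts.diagram["AB"] == 1


class TestSharedWithReference:
    def test_disjoint_excluded_identical_included(self):
        by_pop = {
            "REF": [island("REF", 1, 1_000_000, 2_000_000)],
            "P1": [island("P1", 1, 1_000_000, 2_000_000), island("P1", 2, 1, 100)],
        }
        shared = shared_with_reference(by_pop, "REF")
        assert len(shared["P1"]) == 1
        assert shared["P1"][0].chromosome == 1

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            shared_with_reference({"P1": []}, "REF")

    def test_sharing_symmetric_at_pair_level(self, rng):
        a = [island("A", 1, int(s), int(s) + 400_000) for s in rng.integers(1, 30_000_000, 8)]
        b = [island("B", 1, int(s), int(s) + 400_000) for s in rng.integers(1, 30_000_000, 8)]
        ab = shared_with_reference({"A": a, "B": b}, "A")["B"]
        ba = shared_with_reference({"A": a, "B": b}, "B")["A"]
        assert (len(ab) > 0) == (len(ba) > 0)


class TestEndToEnd:
    def test_islands_for_population_pipeline(self):
        markers = make_markers((np.arange(500) + 1) * 10_000)
        segs = [
            RohSegment(sample=f"i{k}", chromosome=1, start_bp=1_000_000, end_bp=1_400_000, n_snps=41)
            for k in range(9)
        ]
        islands = islands_for_population(segs, markers, [f"i{k}" for k in range(10)], "pop")
        assert len(islands) >= 1
        assert all(1_000_000 <= i.start_bp <= i.end_bp <= 1_400_000 for i in islands)
        assert all(i.peak_incidence == pytest.approx(0.9) for i in islands)
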