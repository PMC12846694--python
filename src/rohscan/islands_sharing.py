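"""ROH islands: per-SNP incidence, top-1% hotspots, and cross-group sharing.

For each population the fraction of individuals whose ROH cover each
marker is computed (an individual contributes at most once per marker).
Markers at or above the (1 - top_fraction) quantile of that incidence
spectrum are hotspots; the quantile cut includes ties, so the hotspot set
is never an arbitrary subset of equally frequent markers.  Maximal runs
of hotspot markers (gaps <= max_gap_bp) become island segments, which are
intersected across populations — "shared" means >= 1 bp of overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import MarkerMap
from .roh_detection import RohSegment


@dataclass(frozen=True)
class SnpIncidenceTrack:
    """Per-marker fraction of a population's individuals inside an ROH."""

    population: str
    markers: MarkerMap
    incidence: np.ndarray  # float in [0, 1], one value per marker

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=float)
        object.__setattr__(self, "incidence", inc)
        if len(inc) != len(self.markers):
            raise ValueError("incidence length != marker count")
        if len(inc) and (inc.min() < 0 or inc.max() > 1):
            raise ValueError("incidence outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        frame = self.markers.to_frame()
        frame["incidence"] = self.incidence
        frame.insert(0, "population", self.population)
        return frame


@dataclass(frozen=True)
class IslandSegment:
    """Merged run of hotspot markers (1-based inclusive bp span)."""

    population: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_hotspot_snps: int
    peak_incidence: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


def _check_no_overlap(segments: Sequence[RohSegment]) -> None:
    by_key: dict[tuple[str, int], list[RohSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample, s.chromosome), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping ROH segments for {sample} chr{chrom}: "
                    f"{a.start_bp}-{a.end_bp} vs {b.start_bp}-{b.end_bp}"
                )


def snp_incidence(
    segments: Sequence[RohSegment],
    markers: MarkerMap,
    population_samples: Sequence[str],
    population: str = "pop",
) -> SnpIncidenceTrack:
    """Fraction of the population covered by an ROH at each marker."""
    if len(population_samples) == 0:
        raise ValueError(f"population {population!r} has no individuals")
    pop = set(population_samples)
    own = [s for s in segments if s.sample in pop]
    _check_no_overlap(own)
    counts = np.zeros(len(markers), dtype=np.int64)
    slices = markers.chromosome_slices()
    for s in own:
        sl = slices.get(s.chromosome)
        if sl is None:
            continue
        pos = markers.positions[sl]
        lo = int(np.searchsorted(pos, s.start_bp, side="left"))
        hi = int(np.searchsorted(pos, s.end_bp, side="right"))
        counts[sl.start + lo : sl.start + hi] += 1
    return SnpIncidenceTrack(
        population=population, markers=markers, incidence=counts / len(pop)
    )


def call_hotspots(track: SnpIncidenceTrack, top_fraction: float = 0.01) -> np.ndarray:
    """Indices of hotspot markers: the top fraction of the incidence spectrum.

    The threshold is the (1 - top_fraction) quantile; markers tied at the
    threshold are all included.  Zero-incidence markers never qualify.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    inc = track.incidence
    if len(inc) == 0 or inc.max() == 0:
        warnings.warn(f"all-zero incidence track for {track.population!r}; no hotspots")
        return np.empty(0, dtype=np.int64)
    threshold = float(np.quantile(inc, 1.0 - top_fraction))
    if len(np.unique(inc)) == 1:
        warnings.warn(
            f"degenerate incidence track for {track.population!r}: all markers tied"
        )
    hot = (inc >= threshold) & (inc > 0)
    return np.flatnonzero(hot)


def build_islands(
    hotspots: np.ndarray,
    markers: MarkerMap,
    max_gap_bp: int = 500_000,
    population: str = "pop",
    incidence: np.ndarray | None = None,
) -> list[IslandSegment]:
    """Merge hotspot markers into island segments.

    Runs of hotspot markers consecutive in map order on one chromosome,
    with inter-marker gaps <= max_gap_bp, span first to last hotspot
    position.  An isolated hotspot yields a zero-length island
    (start == end), which is retained.
    """
    hotspots = np.asarray(hotspots, dtype=np.int64)
    out: list[IslandSegment] = []
    if len(hotspots) == 0:
        return out
    hotspots = np.sort(hotspots)
    chrom = markers.chromosomes[hotspots]
    pos = markers.positions[hotspots]
    breaks = np.flatnonzero(
        (np.diff(hotspots) != 1) | (np.diff(chrom) != 0) | (np.diff(pos) > max_gap_bp)
    )
    for run in np.split(np.arange(len(hotspots)), breaks + 1):
        idx = hotspots[run]
        peak = float(np.max(incidence[idx])) if incidence is not None else float("nan")
        out.append(
            IslandSegment(
                population=population,
                chromosome=int(chrom[run[0]]),
                start_bp=int(pos[run[0]]),
                end_bp=int(pos[run[-1]]),
                n_hotspot_snps=len(run),
                peak_incidence=peak,
            )
        )
    return out


def islands_for_population(
    segments: Sequence[RohSegment],
    markers: MarkerMap,
    population_samples: Sequence[str],
    population: str,
    top_fraction: float = 0.01,
    max_gap_bp: int = 500_000,
) -> list[IslandSegment]:
    """Incidence -> hotspots -> islands for one population in one call."""
    track = snp_incidence(segments, markers, population_samples, population)
    hot = call_hotspots(track, top_fraction)
    return build_islands(hot, markers, max_gap_bp, population, track.incidence)


def _tree_of(islands: Iterable[IslandSegment]) -> dict[int, IntervalTree]:
    trees: dict[int, IntervalTree] = {}
    for isl in islands:
        # half-open [start, end+1) so 1 bp islands and 1 bp overlaps register
        trees.setdefault(isl.chromosome, IntervalTree()).addi(isl.start_bp, isl.end_bp + 1, isl)
    return trees


def _overlaps_any(isl: IslandSegment, trees: dict[int, IntervalTree]) -> bool:
    tree = trees.get(isl.chromosome)
    return bool(tree is not None and tree.overlap(isl.start_bp, isl.end_bp + 1))


@dataclass(frozen=True)
class VennCounts:
    """Three-set region counts over island segments.

    Each group's islands partition into four regions (exclusive, two
    pairwise, triple) by which other groups they overlap; the seven
    diagram counts are reported from the first-listed group of each
    region (AB from A, AC from A, BC from B, ABC from A).
    """

    set_names: tuple[str, str, str]
    regions_by_group: dict[str, dict[str, int]]

    @property
    def totals(self) -> dict[str, int]:
        return {g: sum(r.values()) for g, r in self.regions_by_group.items()}

    @property
    def diagram(self) -> dict[str, int]:
        a, b, c = self.set_names
        return {
            "only_A": self.regions_by_group[a]["exclusive"],
            "only_B": self.regions_by_group[b]["exclusive"],
            "only_C": self.regions_by_group[c]["exclusive"],
            "AB": self.regions_by_group[a]["with_B"],
            "AC": self.regions_by_group[a]["with_C"],
            "BC": self.regions_by_group[b]["with_C"],
            "ABC": self.regions_by_group[a]["with_BC"],
        }


def venn_segments(
    islands_by_group: Mapping[str, Sequence[IslandSegment]]
) -> VennCounts:
    """Assign each group's islands to the four regions of a 3-set diagram.

    A segment of group A is "shared" with group B iff it overlaps >= 1 bp
    with any island of B.
    """
    names = tuple(islands_by_group)
    if len(names) != 3:
        raise ValueError("venn_segments needs exactly three groups")
    trees = {g: _tree_of(islands_by_group[g]) for g in names}
    regions: dict[str, dict[str, int]] = {}
    for gi, g in enumerate(names):
        others = [n for n in names if n != g]
        counts = {"exclusive": 0, "with_B": 0, "with_C": 0, "with_BC": 0}
        for isl in islands_by_group[g]:
            hits = tuple(_overlaps_any(isl, trees[o]) for o in others)
            if hits == (False, False):
                counts["exclusive"] += 1
            elif hits == (True, False):
                counts["with_B"] += 1
            elif hits == (False, True):
                counts["with_C"] += 1
            else:
                counts["with_BC"] += 1
        regions[g] = counts
    return VennCounts(set_names=names, regions_by_group=regions)


def shared_with_reference(
    islands_by_population: Mapping[str, Sequence[IslandSegment]], reference: str
) -> dict[str, list[IslandSegment]]:
    """Islands of each non-reference population overlapping the reference.

    Overlap is >= 1 bp with any island of the reference population; the
    full island span (and hence its constituent markers) is retained for
    downstream annotation.
    """
    if reference not in islands_by_population:
        raise ValueError(f"reference population {reference!r} absent")
    ref_trees = _tree_of(islands_by_population[reference])
    out: dict[str, list[IslandSegment]] = {}
    for pop, islands in islands_by_population.items():
        if pop == reference:
            continue
        out[pop] = [isl for isl in islands if _overlaps_any(isl, ref_trees)]
    return out


def islands_frame(islands: Iterable[IslandSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": i.population,
                "chrom": i.chromosome,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "n_hotspot_snps": i.n_hotspot_snps,
                "peak_incidence": i.peak_incidence,
            }
            for i in islands
        ],
        columns=["population", "chrom", "start_bp", "end_bp", "n_hotspot_snps", "peak_incidence"],
    )
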