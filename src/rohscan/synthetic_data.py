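"""Synthetic multi-breed SNP panels with implanted autozygous tracts.

The generator emulates a medium-density genotyping panel over pig
autosomes: evenly spaced markers, per-breed allele frequencies drawn
uniformly from [0.05, 0.5], background genotypes sampled under
Hardy-Weinberg equilibrium at those frequencies, and autozygous tracts
implanted by doubling a founder haplotype (every marker in the tract
forced homozygous).  Missingness and genotype errors are applied after
implantation; the tract coordinates recorded as ground truth are
pre-noise.  Markers are independent given their frequencies — background
linkage disequilibrium is deliberately not simulated, so short-ROH
behaviour of real arrays is not reproduced (tracts here are the only
source of long homozygosity).

The default panel is desk-scale: 2 chromosomes x 2,000 markers at 50 kb
spacing, 60 individuals in 4 breeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, SampleTable, GROUP_LABELS
from .roh_detection import RohSegment

#: Minimum separation enforced between two implanted tracts of one carrier,
#: keeping truth tracts unambiguous for recovery scoring.
TRACT_MIN_SEPARATION_BP = 2_000_000


@dataclass(frozen=True)
class TractSpec:
    """Implantation recipe for one breed.

    ``lengths_bp`` fixes the exact tract lengths given to every carrier
    (overriding the uniform range); otherwise each tract length is drawn
    uniformly from ``length_bp_range``.
    """

    breed: str
    carrier_fraction: float = 1.0
    tracts_per_carrier: int = 1
    length_bp_range: tuple[int, int] = (1_000_000, 80_000_000)
    lengths_bp: tuple[int, ...] | None = None
    #: fixed (chromosome, start_bp) for the first tract of every carrier —
    #: implants a shared hotspot locus so ROH islands coincide across breeds
    at: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction outside [0, 1]")
        if self.lengths_bp is None and self.length_bp_range[0] > self.length_bp_range[1]:
            raise ValueError("invalid length range")


@dataclass(frozen=True)
class SimParams:
    """Panel geometry, breed structure, noise rates and implantation plan."""

    n_chromosomes: int = 2
    markers_per_chromosome: int = 2_000
    chromosome_length_bp: int = 100_000_000
    n_breeds: int = 4
    individuals_per_breed: int = 15
    freq_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    tract_spec: tuple[TractSpec, ...] = ()
    seed: int = 0
    breed_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.missing_rate > 0.10:
            raise ValueError("missing_rate above the 10% panel ceiling")
        if self.chromosome_length_bp // self.markers_per_chromosome < 1:
            raise ValueError("marker spacing must be positive")

    @property
    def spacing_bp(self) -> int:
        return self.chromosome_length_bp // self.markers_per_chromosome

    @property
    def breeds(self) -> tuple[str, ...]:
        if self.breed_names is not None:
            if len(self.breed_names) != self.n_breeds:
                raise ValueError("breed_names length != n_breeds")
            return self.breed_names
        return tuple(f"BR{i + 1:02d}" for i in range(self.n_breeds))


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated panel (pre-noise)."""

    tracts: pd.DataFrame  # sample, breed, chrom, start_bp, end_bp, length_bp
    markers: MarkerMap
    samples: SampleTable
    planted_genes: pd.DataFrame | None = None
    #: fixed hotspot loci implanted across carriers: breed, chrom, start_bp
    planted_hotspots: pd.DataFrame | None = None

    def tracts_of(self, sample: str) -> pd.DataFrame:
        return self.tracts[self.tracts["sample"] == sample]


def _build_markers(params: SimParams) -> MarkerMap:
    spacing = params.spacing_bp
    per = params.markers_per_chromosome
    chroms = np.repeat(np.arange(1, params.n_chromosomes + 1, dtype=np.int32), per)
    pos_one = spacing * np.arange(per, dtype=np.int64) + 1
    positions = np.tile(pos_one, params.n_chromosomes)
    ids = tuple(f"snp_{c}_{p}" for c, p in zip(chroms, positions))
    return MarkerMap(ids=ids, chromosomes=chroms, positions=positions)


def _place_tract(
    rng: np.random.Generator,
    params: SimParams,
    length: int,
    existing: list[tuple[int, int, int]],
) -> tuple[int, int, int]:
    """Draw a (chrom, start, end) keeping separation from existing tracts."""
    if length > params.chromosome_length_bp:
        raise ValueError(f"tract of {length} bp exceeds chromosome length")
    for _ in range(200):
        chrom = int(rng.integers(1, params.n_chromosomes + 1))
        start = int(rng.integers(1, params.chromosome_length_bp - length + 2))
        end = start + length - 1
        ok = all(
            c != chrom or start > e + TRACT_MIN_SEPARATION_BP or end < s - TRACT_MIN_SEPARATION_BP
            for c, s, e in existing
        )
        if ok:
            return chrom, start, end
    raise ValueError("could not place tract without collisions; too much implantation")


def simulate_panel(params: SimParams) -> tuple[GenotypeMatrix, MarkerMap, SampleTable, SyntheticTruth]:
    """Generate the panel; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    markers = _build_markers(params)
    n_markers = len(markers)
    breeds = params.breeds

    sample_names: list[str] = []
    breed_rows: list[dict] = []
    for bi, breed in enumerate(breeds):
        group = GROUP_LABELS[bi % len(GROUP_LABELS)]
        for k in range(params.individuals_per_breed):
            name = f"{breed}_{k + 1:03d}"
            sample_names.append(name)
            breed_rows.append(
                {
                    "sample": name,
                    "breed": breed,
                    "group": group,
                    "category": "cosmopolitan" if group == "Cosmopolitan" else "indigenous",
                }
            )
    samples = SampleTable(pd.DataFrame(breed_rows))

    lo, hi = params.freq_range
    freqs = rng.uniform(lo, hi, size=(len(breeds), n_markers))
    calls = np.empty((len(sample_names), n_markers), dtype=np.int8)
    for bi in range(len(breeds)):
        rows = slice(bi * params.individuals_per_breed, (bi + 1) * params.individuals_per_breed)
        calls[rows] = rng.binomial(2, freqs[bi], size=(params.individuals_per_breed, n_markers))

    # implant autozygous tracts: double a founder haplotype
    truth_rows: list[dict] = []
    sample_index = {s: i for i, s in enumerate(sample_names)}
    chrom_offsets = {c: sl.start for c, sl in markers.chromosome_slices().items()}
    positions_one = markers.positions[: params.markers_per_chromosome]
    for spec in params.tract_spec:
        if spec.breed not in breeds:
            raise ValueError(f"tract spec names unknown breed {spec.breed!r}")
        bi = breeds.index(spec.breed)
        members = [s for s in sample_names if s.startswith(spec.breed + "_")]
        n_carriers = int(round(spec.carrier_fraction * len(members)))
        carriers = list(rng.choice(members, size=n_carriers, replace=False))
        for carrier in carriers:
            placed: list[tuple[int, int, int]] = []
            if spec.lengths_bp is not None:
                lengths = list(spec.lengths_bp)
            else:
                lengths = [
                    int(rng.integers(spec.length_bp_range[0], spec.length_bp_range[1] + 1))
                    for _ in range(spec.tracts_per_carrier)
                ]
            for ti, length in enumerate(lengths):
                if ti == 0 and spec.at is not None:
                    chrom, start = spec.at
                    end = start + length - 1
                    if end > params.chromosome_length_bp:
                        raise ValueError("fixed-position tract exceeds chromosome length")
                else:
                    chrom, start, end = _place_tract(rng, params, length, placed)
                placed.append((chrom, start, end))
                j0 = int(np.searchsorted(positions_one, start, side="left"))
                j1 = int(np.searchsorted(positions_one, end, side="right"))
                cols = slice(chrom_offsets[chrom] + j0, chrom_offsets[chrom] + j1)
                founder = rng.binomial(1, freqs[bi, cols])
                calls[sample_index[carrier], cols] = (2 * founder).astype(np.int8)
                truth_rows.append(
                    {
                        "sample": carrier,
                        "breed": spec.breed,
                        "chrom": chrom,
                        "start_bp": start,
                        "end_bp": end,
                        "length_bp": length,
                    }
                )

    # noise, applied after implantation
    if params.genotype_error_rate > 0:
        flip = rng.random(calls.shape) < params.genotype_error_rate
        hom_to = rng.integers(0, 2, size=calls.shape) * 2  # 0 or 2
        flipped = np.where(calls == 1, hom_to, 1).astype(np.int8)
        calls = np.where(flip & (calls != MISSING), flipped, calls).astype(np.int8)
    if params.missing_rate > 0:
        mask = rng.random(calls.shape) < params.missing_rate
        calls[mask] = MISSING

    geno = GenotypeMatrix(samples=tuple(sample_names), markers=markers, calls=calls)
    hotspots = pd.DataFrame(
        [
            {"breed": s.breed, "chrom": s.at[0], "start_bp": s.at[1]}
            for s in params.tract_spec
            if s.at is not None
        ],
        columns=["breed", "chrom", "start_bp"],
    )
    truth = SyntheticTruth(
        tracts=pd.DataFrame(
            truth_rows, columns=["sample", "breed", "chrom", "start_bp", "end_bp", "length_bp"]
        ),
        markers=markers,
        samples=samples,
        planted_hotspots=hotspots if len(hotspots) else None,
    )
    return geno, markers, samples, truth


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    precision: float
    boundary_error_bp: float
    n_truth: int
    n_called: int
    n_recovered: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def score_recovery(
    called: Sequence[RohSegment],
    truth: SyntheticTruth,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryScore:
    """Sensitivity, precision and mean endpoint offset of the calls.

    A truth tract is recovered if some called segment of the same
    individual and chromosome reciprocally overlaps it by at least
    ``min_reciprocal_overlap``; boundary error averages |called - true|
    endpoint offsets of the best-overlapping call per recovered tract.
    """
    by_carrier: dict[tuple[str, int], list[RohSegment]] = {}
    for seg in called:
        by_carrier.setdefault((seg.sample, seg.chromosome), []).append(seg)

    n_truth = len(truth.tracts)
    n_recovered = 0
    offsets: list[float] = []
    matched_calls: set[int] = set()
    for row in truth.tracts.itertuples(index=False):
        candidates = by_carrier.get((row.sample, row.chrom), [])
        best, best_ov = None, 0.0
        for seg in candidates:
            ov = _reciprocal_overlap(seg.start_bp, seg.end_bp, row.start_bp, row.end_bp)
            if ov > best_ov:
                best, best_ov = seg, ov
        if best is not None and best_ov >= min_reciprocal_overlap:
            n_recovered += 1
            matched_calls.add(id(best))
            offsets.append((abs(best.start_bp - row.start_bp) + abs(best.end_bp - row.end_bp)) / 2)

    # precision: a call is true if it reciprocally overlaps any truth tract
    n_called = len(called)
    n_true_calls = 0
    truth_by_carrier: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for row in truth.tracts.itertuples(index=False):
        truth_by_carrier.setdefault((row.sample, row.chrom), []).append((row.start_bp, row.end_bp))
    for seg in called:
        spans = truth_by_carrier.get((seg.sample, seg.chromosome), [])
        if any(
            _reciprocal_overlap(seg.start_bp, seg.end_bp, s, e) >= min_reciprocal_overlap
            for s, e in spans
        ):
            n_true_calls += 1

    return RecoveryScore(
        sensitivity=n_recovered / n_truth if n_truth else float("nan"),
        precision=n_true_calls / n_called if n_called else float("nan"),
        boundary_error_bp=float(np.mean(offsets)) if offsets else 0.0,
        n_truth=n_truth,
        n_called=n_called,
        n_recovered=n_recovered,
    )


# ---------------------------------------------------------------------------
# Synthetic gene models (for annotation round trips)
# ---------------------------------------------------------------------------

def write_synthetic_gff(
    genes: Sequence[tuple[str, int, int, int]], path: str | Path, dialect: str = "gff3"
) -> None:
    """Write (name, chrom, start_bp, end_bp) gene models as GFF3 or GTF.

    Synthetic stand-in for a genome annotation; coordinates are 1-based
    inclusive as in real GFF/GTF.
    """
    path = Path(path)
    lines = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
        for name, chrom, start, end in genes:
            lines.append(
                f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID=gene:{name};Name={name}"
            )
    elif dialect == "gtf":
        for name, chrom, start, end in genes:
            attrs = f'gene_id "{name}"; gene_name "{name}";'
            lines.append(f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("".join(line + "\n" for line in lines))
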