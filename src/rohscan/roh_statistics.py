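"""Per-individual and per-breed ROH descriptive statistics and FROH.

FROH — the genomic inbreeding coefficient — is the fraction of the
autosomal panel span covered by an individual's ROH:
``FROH = L_ROH / L_AUTO``, where L_ROH is the summed segment length and
L_AUTO the summed per-chromosome physical span of the marker panel.

Segments are binned into five length classes (1-5, 5-10, 10-20, 20-40
and >40 Mb) with half-open bins closed on the left, so a segment of
exactly 5 Mb falls in the 5-10 class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .roh_detection import RohSegment

LENGTH_CLASSES = ("1-5", "5-10", "10-20", "20-40", ">40")
_CLASS_EDGES_MB = (1.0, 5.0, 10.0, 20.0, 40.0)


def classify_length(length_bp: int) -> str:
    """Length-class label for a segment; half-open bins, boundaries upward."""
    mb = length_bp / 1e6
    if mb < 1.0:
        raise ValueError(f"segment of {length_bp} bp is below the 1 Mb reporting floor")
    for label, lo, hi in zip(LENGTH_CLASSES[:-1], _CLASS_EDGES_MB[:-1], _CLASS_EDGES_MB[1:]):
        if lo <= mb < hi:
            return label
    return LENGTH_CLASSES[-1]


@dataclass(frozen=True)
class IndividualRohSummary:
    sample: str
    breed_code: str
    n_segments: int
    total_length_bp: int  # L_ROH
    mean_length_mb: float
    f_roh: float


def summarize_individual(
    segments: Sequence[RohSegment], l_auto_bp: int, sample: str | None = None, breed_code: str = "."
) -> IndividualRohSummary:
    """Count, total length, mean length and FROH for one individual."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    owners = {s.sample for s in segments}
    if len(owners) > 1:
        raise ValueError(f"segments belong to several samples: {sorted(owners)}")
    if sample is None:
        if not owners:
            raise ValueError("sample must be given when the segment list is empty")
        sample = owners.pop()
    total = sum(s.length_bp for s in segments)
    n = len(segments)
    return IndividualRohSummary(
        sample=sample,
        breed_code=breed_code,
        n_segments=n,
        total_length_bp=total,
        mean_length_mb=(total / n / 1e6) if n else 0.0,
        f_roh=total / l_auto_bp,
    )


@dataclass(frozen=True)
class BreedRohSummary:
    breed_code: str
    sample_size: int
    class_counts: dict[str, int]
    mean_length_mb: float
    sd_length_mb: float
    range_length_mb: tuple[float, float]
    mean_n_segments: float
    sd_n_segments: float
    range_n_segments: tuple[int, int]
    mean_f_roh: float
    sd_f_roh: float
    range_f_roh: tuple[float, float]
    sd_degenerate: bool  # single individual: sd reported as 0 with this flag

    @property
    def total_segments(self) -> int:
        return sum(self.class_counts.values())


def _mean_sd_range(values: np.ndarray) -> tuple[float, float, tuple[float, float], bool]:
    if len(values) == 1:
        return float(values[0]), 0.0, (float(values[0]), float(values[0])), True
    return (
        float(values.mean()),
        float(values.std(ddof=1)),
        (float(values.min()), float(values.max())),
        False,
    )


def summarize_breed(
    per_individual: Sequence[IndividualRohSummary], segments: Sequence[RohSegment]
) -> BreedRohSummary:
    """Breed-level statistics: class counts and mean +/- sd (n-1) with ranges.

    Per-individual mean segment length is averaged over individuals that
    carry at least one segment; class counts are over all of the breed's
    segments.
    """
    if not per_individual:
        raise ValueError("empty breed")
    breeds = {r.breed_code for r in per_individual}
    if len(breeds) != 1:
        raise ValueError(f"records from several breeds: {sorted(breeds)}")
    breed = breeds.pop()
    own_samples = {r.sample for r in per_individual}
    foreign = {s.sample for s in segments} - own_samples
    if foreign:
        raise ValueError(f"segments from samples outside the breed: {sorted(foreign)[:5]}")

    counts = dict.fromkeys(LENGTH_CLASSES, 0)
    for s in segments:
        counts[classify_length(s.length_bp)] += 1

    lengths = np.array([r.mean_length_mb for r in per_individual if r.n_segments > 0])
    if len(lengths) == 0:
        lengths = np.array([0.0])
    n_seg = np.array([r.n_segments for r in per_individual])
    froh = np.array([r.f_roh for r in per_individual])

    mean_l, sd_l, rng_l, deg_l = _mean_sd_range(lengths)
    mean_n, sd_n, rng_n, deg_n = _mean_sd_range(n_seg.astype(float))
    mean_f, sd_f, rng_f, deg_f = _mean_sd_range(froh)
    return BreedRohSummary(
        breed_code=breed,
        sample_size=len(per_individual),
        class_counts=counts,
        mean_length_mb=mean_l,
        sd_length_mb=sd_l,
        range_length_mb=rng_l,
        mean_n_segments=mean_n,
        sd_n_segments=sd_n,
        range_n_segments=(int(rng_n[0]), int(rng_n[1])),
        mean_f_roh=mean_f,
        sd_f_roh=sd_f,
        range_f_roh=rng_f,
        sd_degenerate=deg_l or deg_n or deg_f,
    )


def summarize_panel(
    segments: Sequence[RohSegment],
    breed_of: dict[str, str],
    l_auto_bp: int,
    all_samples: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual- and breed-level summary frames for a whole panel.

    ``all_samples`` lists every genotyped individual so that samples with
    zero called segments still enter the breed means with FROH = 0.
    """
    samples = list(all_samples) if all_samples is not None else sorted({s.sample for s in segments})
    by_sample: dict[str, list[RohSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)

    indiv = [
        summarize_individual(by_sample[s], l_auto_bp, sample=s, breed_code=breed_of.get(s, "."))
        for s in samples
    ]
    indiv_frame = pd.DataFrame(
        {
            "sample": [r.sample for r in indiv],
            "breed": [r.breed_code for r in indiv],
            "n_segments": [r.n_segments for r in indiv],
            "l_roh_bp": [r.total_length_bp for r in indiv],
            "mean_length_mb": [round(r.mean_length_mb, 2) for r in indiv],
            "f_roh": [r.f_roh for r in indiv],
        }
    )

    rows = []
    for breed in sorted({r.breed_code for r in indiv}):
        recs = [r for r in indiv if r.breed_code == breed]
        segs = [s for r in recs for s in by_sample[r.sample]]
        b = summarize_breed(recs, segs)
        row = {
            "breed": b.breed_code,
            "sample_size": b.sample_size,
            "mean_length_mb": round(b.mean_length_mb, 2),
            "sd_length_mb": round(b.sd_length_mb, 2),
            "mean_n_segments": round(b.mean_n_segments, 2),
            "sd_n_segments": round(b.sd_n_segments, 2),
            "mean_f_roh": round(b.mean_f_roh, 4),
            "sd_f_roh": round(b.sd_f_roh, 4),
        }
        row.update({f"class_{c}": b.class_counts[c] for c in LENGTH_CLASSES})
        rows.append(row)
    return indiv_frame, pd.DataFrame(rows)


def chromosome_distribution(
    segments: Sequence[RohSegment], breed_of: dict[str, str], chromosomes: Iterable[int] = range(1, 19)
) -> pd.DataFrame:
    """Segment counts per (breed, chromosome), zero-filled."""
    chroms = list(chromosomes)
    breeds = sorted(set(breed_of.values()))
    table = pd.DataFrame(0, index=pd.Index(breeds, name="breed"), columns=chroms)
    for s in segments:
        b = breed_of.get(s.sample)
        if b is not None and s.chromosome in table.columns:
            table.loc[b, s.chromosome] += 1
    return table


# ---------------------------------------------------------------------------
# Bundled reference class counts (24-breed 50K pig panel)
# ---------------------------------------------------------------------------

def load_reference_class_counts() -> pd.DataFrame:
    """Breed x length-class ROH counts for a published 24-breed pig panel.

    Used as a reporting fixture: aggregating it through the class machinery
    must reproduce the panel's printed class totals and percentages.
    """
    with resources.files("rohscan").joinpath("data/breed_roh_class_counts.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    frame.columns = ["breed", *LENGTH_CLASSES]
    return frame


def aggregate_class_counts(per_breed: pd.DataFrame) -> pd.DataFrame:
    """Panel-wide class totals and percentage shares from per-breed counts.

    Exercised through :func:`summarize_breed`: each breed row is expanded
    into representative segments, summarised, and re-aggregated, so the
    totals really flow through the reporting machinery.
    """
    class_mid_bp = {"1-5": 3_000_000, "5-10": 7_000_000, "10-20": 15_000_000,
                    "20-40": 30_000_000, ">40": 50_000_000}
    totals = dict.fromkeys(LENGTH_CLASSES, 0)
    for _, row in per_breed.iterrows():
        segs = []
        for ci, label in enumerate(LENGTH_CLASSES):
            # one chromosome per class keeps the representative segments disjoint
            segs.extend(
                RohSegment(
                    sample=f"{row['breed']}_pooled",
                    chromosome=ci + 1,
                    start_bp=1 + k * 60_000_000,
                    end_bp=class_mid_bp[label] + k * 60_000_000,
                    n_snps=100,
                )
                for k in range(int(row[label]))
            )
        rec = summarize_individual(segs, l_auto_bp=10**12, sample=f"{row['breed']}_pooled",
                                   breed_code=str(row["breed"]))
        b = summarize_breed([rec], segs)
        for label in LENGTH_CLASSES:
            totals[label] += b.class_counts[label]
    grand = sum(totals.values())
    return pd.DataFrame(
        {
            "length_class": LENGTH_CLASSES,
            "n_segments": [totals[c] for c in LENGTH_CLASSES],
            "pct": [round(100.0 * totals[c] / grand, 1) if grand else 0.0 for c in LENGTH_CLASSES],
        }
    )
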