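"""Marker, sample and breed quality-control filters, plus L_AUTO.

Filter order is fixed: sample missingness -> SNP call rate -> MAF ->
breed size.  PLINK applies sample and marker filters jointly, so boundary
cases can differ slightly from a PLINK run with the same thresholds; the
order used here is deterministic and documented.  MAF is computed on
non-missing calls only.  Heterozygosity outliers are flagged, never
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, SampleTable


class EmptyAfterQcError(ValueError):
    """All samples or all markers were removed by the filters."""


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the marker/sample/breed filters.

    Defaults mirror a standard 50K-array workflow: drop markers with
    MAF < 0.05 or call rate < 90%, samples with > 10% missing genotypes,
    and breeds left with fewer than five individuals.  Heterozygosity
    outliers beyond ``het_outlier_sd`` standard deviations are flagged only.
    """

    maf_min: float = 0.05
    snp_call_rate_min: float = 0.90
    sample_missing_max: float = 0.10
    breed_min_n: int = 5
    het_outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_rate_min", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.breed_min_n < 1:
            raise ValueError("breed_min_n must be >= 1")


@dataclass
class QcReport:
    snps_removed_maf: int = 0
    snps_removed_callrate: int = 0
    samples_removed_missing: int = 0
    breeds_removed: list[str] = field(default_factory=list)
    samples_removed_breed: int = 0
    het_flagged: list[str] = field(default_factory=list)
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_final: int = 0
    n_snps_final: int = 0
    l_auto_bp: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_samples_in", "n_snps_in", "samples_removed_missing",
                    "snps_removed_callrate", "snps_removed_maf",
                    "samples_removed_breed", "breeds_removed", "het_flagged",
                    "n_samples_final", "n_snps_final", "l_auto_bp",
                ],
                "value": [
                    self.n_samples_in, self.n_snps_in, self.samples_removed_missing,
                    self.snps_removed_callrate, self.snps_removed_maf,
                    self.samples_removed_breed, ",".join(self.breeds_removed) or ".",
                    ",".join(self.het_flagged) or ".",
                    self.n_samples_final, self.n_snps_final, self.l_auto_bp,
                ],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_l_auto(markers: MarkerMap) -> int:
    """Total autosomal span covered by the panel.

    Sum over chromosomes of (last marker position - first marker position
    + 1), 1-based inclusive; a chromosome with a single marker contributes 1.
    """
    if len(markers) == 0:
        raise ValueError("empty marker map")
    total = 0
    for sl in markers.chromosome_slices().values():
        pos = markers.positions[sl]
        total += int(pos.max() - pos.min() + 1)
    return total


def individual_heterozygosity(geno: GenotypeMatrix, het_outlier_sd: float = 3.0) -> pd.DataFrame:
    """Per-sample heterozygosity rate with outlier flags.

    het_rate = heterozygous calls / non-missing calls.  Samples beyond
    ``het_outlier_sd`` sample standard deviations from the mean, or with no
    non-missing calls at all, are flagged; nothing is removed here.
    """
    if geno.n_samples == 0:
        raise ValueError("empty genotype matrix")
    non_missing = (geno.calls != MISSING).sum(axis=1)
    het = (geno.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(non_missing > 0, het / np.maximum(non_missing, 1), np.nan)
    finite = rate[np.isfinite(rate)]
    if len(finite) >= 2 and finite.std(ddof=1) > 0:
        mu, sd = finite.mean(), finite.std(ddof=1)
        outlier = np.abs(rate - mu) > het_outlier_sd * sd
    else:
        outlier = np.zeros(len(rate), dtype=bool)
    flagged = ~np.isfinite(rate) | np.where(np.isfinite(rate), outlier, False)
    return pd.DataFrame(
        {"sample": list(geno.samples), "het_rate": rate, "flagged": flagged}
    )


def _minor_allele_freq(calls: np.ndarray) -> np.ndarray:
    """Per-marker MAF over non-missing calls; markers with no calls get 0."""
    valid = calls != MISSING
    n_alleles = 2 * valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    geno: GenotypeMatrix, samples: SampleTable, params: QcParams = QcParams()
) -> tuple[GenotypeMatrix, SampleTable, QcReport]:
    """Run the full filter cascade and report what was removed.

    Order: (1) samples above the missingness cap, (2) markers below the
    call-rate floor, (3) markers below the MAF floor, (4) whole breeds left
    with fewer than ``breed_min_n`` individuals.  L_AUTO is computed on the
    retained markers.
    """
    report = QcReport(n_samples_in=geno.n_samples, n_snps_in=geno.n_markers)
    breed_of = samples.breed_of()
    missing_names = set(geno.samples) - set(breed_of)
    if missing_names:
        raise ValueError(f"samples absent from sample table: {sorted(missing_names)[:5]}")

    # 1. sample missingness
    miss_rate = (geno.calls == MISSING).mean(axis=1) if geno.n_markers else np.zeros(geno.n_samples)
    keep_s = np.flatnonzero(miss_rate <= params.sample_missing_max)
    report.samples_removed_missing = geno.n_samples - len(keep_s)
    geno = geno.subset(sample_idx=keep_s)
    if geno.n_samples == 0:
        raise EmptyAfterQcError("no samples left after missingness filter")

    # 2. SNP call rate
    call_rate = (geno.calls != MISSING).mean(axis=0)
    keep_m = np.flatnonzero(call_rate >= params.snp_call_rate_min)
    report.snps_removed_callrate = geno.n_markers - len(keep_m)
    geno = geno.subset(marker_idx=keep_m)

    # 3. MAF
    if geno.n_markers:
        maf = _minor_allele_freq(geno.calls)
        keep_m = np.flatnonzero(maf >= params.maf_min)
        report.snps_removed_maf = geno.n_markers - len(keep_m)
        geno = geno.subset(marker_idx=keep_m)
    if geno.n_markers == 0:
        raise EmptyAfterQcError("no markers left after marker filters")

    # 4. breed size
    breeds = np.array([breed_of[s] for s in geno.samples])
    counts = pd.Series(breeds).value_counts()
    small = sorted(counts.index[counts < params.breed_min_n])
    report.breeds_removed = list(small)
    keep_s = np.flatnonzero(~np.isin(breeds, small))
    report.samples_removed_breed = geno.n_samples - len(keep_s)
    geno = geno.subset(sample_idx=keep_s)
    if geno.n_samples == 0:
        raise EmptyAfterQcError("no samples left after breed-size filter")

    het = individual_heterozygosity(geno, params.het_outlier_sd)
    report.het_flagged = het.loc[het["flagged"], "sample"].tolist()
    report.n_samples_final = geno.n_samples
    report.n_snps_final = geno.n_markers
    report.l_auto_bp = compute_l_auto(geno.markers)
    return geno, samples.subset(geno.samples), report
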