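"""PLINK-format genotype I/O and the internal genotype data model.

Genotypes are held as a dense ``int8`` matrix coded 0 (homozygous for the
first allele, A1), 1 (heterozygous), 2 (homozygous A2) and -1 (missing).
Allele identity beyond hom/het is never needed downstream — ROH calling
uses only the hom/het/missing distinction — so the biallelic 0/1/2 coding
is the whole model.  Coordinates are 1-based inclusive (PLINK convention)
everywhere; BED interval exports convert to 0-based half-open on write.

Supported dialects: PLINK text (PED/MAP) and PLINK 1 binary (BED/BIM/FAM,
SNP-major).  Only autosomes 1-18 (the pig autosome set) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1
AUTOSOMES: range = range(1, 19)
_VALID_ALLELES = frozenset("ACGT120")

#: PLINK .hom-compatible column order used by :func:`write_roh_table`.
HOM_COLUMNS = ["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP"]


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK text or binary input."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered autosomal marker positions — the coordinate backbone.

    Markers are strictly sorted by (chromosome, position) with no duplicate
    physical coordinates; only autosomes 1-18 are admitted.
    """

    ids: tuple[str, ...]
    chromosomes: np.ndarray  # int32, 1..18
    positions: np.ndarray  # int64, 1-based bp

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosomes, dtype=np.int32)
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "chromosomes", chrom)
        object.__setattr__(self, "positions", pos)
        if not (len(self.ids) == len(chrom) == len(pos)):
            raise ValueError("marker map field lengths differ")
        if len(pos) and pos.min() < 1:
            raise ValueError("positions must be >= 1 (1-based)")
        bad = ~np.isin(chrom, list(AUTOSOMES))
        if bad.any():
            raise ValueError(f"non-autosomal chromosome codes: {set(chrom[bad])}")
        key = chrom.astype(np.int64) * 10**10 + pos
        if len(key) > 1 and not (np.diff(key) > 0).all():
            raise ValueError("markers must be strictly sorted by (chrom, pos) without duplicates")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous index slice of each chromosome present in the map."""
        out: dict[int, slice] = {}
        for c in np.unique(self.chromosomes):
            idx = np.flatnonzero(self.chromosomes == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.ids, "chrom": self.chromosomes, "pos": self.positions}
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x markers diploid genotype codes with missingness."""

    samples: tuple[str, ...]
    markers: MarkerMap
    calls: np.ndarray  # int8 (n_samples, n_markers)

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        if calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(self.samples)}, {len(self.markers)})"
            )
        ok = np.isin(calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype codes must be 0/1/2/missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx: np.ndarray | None = None, marker_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        samples = self.samples
        markers = self.markers
        calls = self.calls
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            samples = tuple(np.asarray(samples, dtype=object)[sample_idx])
            calls = calls[sample_idx, :]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            markers = MarkerMap(
                ids=tuple(np.asarray(self.markers.ids, dtype=object)[marker_idx]),
                chromosomes=self.markers.chromosomes[marker_idx],
                positions=self.markers.positions[marker_idx],
            )
            calls = calls[:, marker_idx]
        return GenotypeMatrix(samples=samples, markers=markers, calls=np.ascontiguousarray(calls))


GROUP_LABELS = ("African", "American", "Asian", "European", "Cosmopolitan")


@dataclass(frozen=True)
class SampleTable:
    """Per-sample breed and grouping metadata.

    ``category`` is "cosmopolitan" iff ``group_label`` is Cosmopolitan;
    every genotyped sample appears exactly once.
    """

    frame: pd.DataFrame  # columns: sample, breed, group, category

    def __post_init__(self) -> None:
        required = {"sample", "breed", "group", "category"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"sample table needs columns {sorted(required)}")
        if self.frame["sample"].duplicated().any():
            raise ValueError("duplicate sample identifiers in sample table")
        bad_group = ~self.frame["group"].isin(GROUP_LABELS)
        if bad_group.any():
            raise ValueError(f"unknown group labels: {set(self.frame.loc[bad_group, 'group'])}")
        is_cosmo = self.frame["group"] == "Cosmopolitan"
        want = np.where(is_cosmo, "cosmopolitan", "indigenous")
        if not (self.frame["category"].to_numpy() == want).all():
            raise ValueError("category must be 'cosmopolitan' iff group is Cosmopolitan")

    def __len__(self) -> int:
        return len(self.frame)

    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample"], self.frame["breed"]))

    def samples_of_breed(self, breed: str) -> list[str]:
        return self.frame.loc[self.frame["breed"] == breed, "sample"].tolist()

    def subset(self, samples: Iterable[str]) -> "SampleTable":
        keep = self.frame[self.frame["sample"].isin(set(samples))].reset_index(drop=True)
        return SampleTable(keep)


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the sample→breed TSV (columns: sample, breed, group, category)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP text dialect
# ---------------------------------------------------------------------------

def _read_map(map_path: str | Path) -> tuple[list[str], list[int], list[int], list[bool]]:
    ids: list[str] = []
    chroms: list[int] = []
    poss: list[int] = []
    keep: list[bool] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise PlinkFormatError(f"{map_path}: line {lineno}: expected 4 MAP columns")
            try:
                chrom = int(parts[0].removeprefix("chr"))
                pos = int(parts[3])
            except ValueError as exc:
                raise PlinkFormatError(f"{map_path}: line {lineno}: {exc}") from exc
            ids.append(parts[1])
            chroms.append(chrom)
            poss.append(pos)
            keep.append(chrom in AUTOSOMES)
    return ids, chroms, poss, keep


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK text genotypes, collapsing allele pairs to 0/1/2/missing.

    A1 is the first non-missing allele encountered per marker in file order;
    "0 0" is missing.  Non-autosomal MAP rows are dropped (count logged).
    """
    ids, chroms, poss, keep = _read_map(map_path)
    n_total = len(ids)
    n_dropped = n_total - sum(keep)
    if n_dropped:
        logger.info("dropped %d non-autosomal markers from %s", n_dropped, map_path)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    # first-seen allele per marker establishes A1
    a1: list[str | None] = [None] * n_total
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_total:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_total} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            codes = np.empty(n_total, dtype=np.int8)
            alleles = parts[6:]
            for j in range(n_total):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x not in _VALID_ALLELES or y not in _VALID_ALLELES:
                    raise PlinkFormatError(
                        f"{ped_path}: line {lineno}: invalid allele symbol {x!r}/{y!r} at marker {ids[j]}"
                    )
                if x == "0" or y == "0":
                    codes[j] = MISSING
                    continue
                if a1[j] is None:
                    a1[j] = x
                if x != y:
                    codes[j] = 1
                elif x == a1[j]:
                    codes[j] = 0
                else:
                    codes[j] = 2
            rows.append(codes)

    keep_idx = np.flatnonzero(keep)
    order = np.lexsort((np.asarray(poss)[keep_idx], np.asarray(chroms)[keep_idx]))
    keep_idx = keep_idx[order]
    markers = MarkerMap(
        ids=tuple(ids[i] for i in keep_idx),
        chromosomes=np.asarray(chroms, dtype=np.int32)[keep_idx],
        positions=np.asarray(poss, dtype=np.int64)[keep_idx],
    )
    calls = (
        np.vstack(rows)[:, keep_idx]
        if rows
        else np.empty((0, len(keep_idx)), dtype=np.int8)
    )
    geno = GenotypeMatrix(samples=tuple(samples), markers=markers, calls=calls)
    return geno, markers


def write_ped_map(geno: GenotypeMatrix, prefix: str | Path, breed_of: dict[str, str] | None = None) -> None:
    """Write PLINK text files; code 0 -> "A A", 1 -> "A C", 2 -> "C C"."""
    prefix = Path(prefix)
    m = geno.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp, c, p in zip(m.ids, m.chromosomes, m.positions):
            fh.write(f"{c}\t{snp}\t0\t{p}\n")
    pair = {0: "A A", 1: "A C", 2: "C C", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sample in enumerate(geno.samples):
            fid = breed_of.get(sample, sample) if breed_of else sample
            geno_txt = " ".join(pair[int(g)] for g in geno.calls[i])
            fh.write(f"{fid} {sample} 0 0 0 -9 {geno_txt}\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary dialect (PLINK 1, SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit PLINK codes -> internal: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_bed_bim_fam(prefix: str | Path) -> tuple[GenotypeMatrix, MarkerMap, SampleTable]:
    """Read PLINK 1 binary genotypes (SNP-major).

    The returned :class:`SampleTable` is a stub built from FAM family IDs
    (family ID -> breed, group "American", category "indigenous"); replace it
    with a real sample table when one exists.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "pos": np.int64},
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    bim["chrom"] = bim["chrom"].str.removeprefix("chr").astype(int)
    n_snps_total, n_samples = len(bim), len(fam)

    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major mode")
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * n_snps_total:
        raise PlinkFormatError(f"{prefix}.bed: size mismatch")
    body = body.reshape(n_snps_total, bytes_per_snp)
    # unpack 2-bit fields, sample index runs over the low bits first
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    calls = _BED_DECODE[two_bit.reshape(n_snps_total, -1)[:, :n_samples]].T  # samples x snps

    keep = bim["chrom"].isin(AUTOSOMES).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal markers from %s.bim", n_dropped, prefix)
    bim = bim[keep].reset_index(drop=True)
    calls = calls[:, keep]
    order = np.lexsort((bim["pos"].to_numpy(), bim["chrom"].to_numpy()))
    bim = bim.iloc[order].reset_index(drop=True)
    calls = np.ascontiguousarray(calls[:, order])

    markers = MarkerMap(
        ids=tuple(bim["snp"]),
        chromosomes=bim["chrom"].to_numpy(np.int32),
        positions=bim["pos"].to_numpy(np.int64),
    )
    geno = GenotypeMatrix(samples=tuple(fam["iid"]), markers=markers, calls=calls)
    stub = SampleTable(
        pd.DataFrame(
            {
                "sample": fam["iid"],
                "breed": fam["fid"],
                "group": "American",
                "category": "indigenous",
            }
        )
    )
    return geno, markers, stub


def write_bed_bim_fam(geno: GenotypeMatrix, prefix: str | Path, breed_of: dict[str, str] | None = None) -> None:
    """Write PLINK 1 binary (SNP-major); alleles reported as A/C placeholders."""
    prefix = Path(prefix)
    m = geno.markers
    with open(str(prefix) + ".bim", "w") as fh:
        for snp, c, p in zip(m.ids, m.chromosomes, m.positions):
            fh.write(f"{c}\t{snp}\t0\t{p}\tA\tC\n")
    with open(str(prefix) + ".fam", "w") as fh:
        for sample in geno.samples:
            fid = breed_of.get(sample, sample) if breed_of else sample
            fh.write(f"{fid} {sample} 0 0 0 -9\n")
    n_samples, n_snps = geno.n_samples, geno.n_markers
    bytes_per_snp = (n_samples + 3) // 4
    enc = np.zeros((n_snps, n_samples), dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        enc[geno.calls.T == code] = bits
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = enc
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Interval/segment outputs
# ---------------------------------------------------------------------------

def roh_table(segments: Sequence, breed_of: dict[str, str] | None = None) -> pd.DataFrame:
    """PLINK .hom-shaped frame for ROH segments, sorted (IID, CHR, POS1)."""
    rows = []
    for s in segments:
        rows.append(
            {
                "FID": breed_of.get(s.sample, s.sample) if breed_of else s.sample,
                "IID": s.sample,
                "CHR": s.chromosome,
                "SNP1": s.first_snp,
                "SNP2": s.last_snp,
                "POS1": s.start_bp,
                "POS2": s.end_bp,
                "KB": (s.end_bp - s.start_bp + 1) / 1000.0,
                "NSNP": s.n_snps,
            }
        )
    frame = pd.DataFrame(rows, columns=HOM_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["IID", "CHR", "POS1"], kind="stable").reset_index(drop=True)
    return frame


def write_roh_table(segments: Sequence, out_path: str | Path, breed_of: dict[str, str] | None = None) -> None:
    """Write segments as a PLINK .hom-compatible TSV (1-based inclusive bp)."""
    roh_table(segments, breed_of).to_csv(out_path, sep="\t", index=False)


def write_intervals_bed(intervals: Iterable[tuple[int, int, int, str]], out_path: str | Path) -> None:
    """Write (chrom, start_bp, end_bp, name) 1-based inclusive intervals as BED.

    BED is 0-based half-open, so start is shifted down by one on write.
    """
    with open(out_path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
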