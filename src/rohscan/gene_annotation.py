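"""Gene annotation of ROH islands from a local GFF3/GTF.

Each hotspot SNP contributes a window of +/- ``flank_bp`` (default 50 kb,
i.e. a 100 kb region) around its position; each island contributes its
span extended by the same flank.  A gene is reported when its span
overlaps a window by at least 1 bp.  Strand is ignored: the windows are
symmetric and SNPs are strandless.  Gene lists are deduplicated per
region and per group, and exported as plain text suitable for pasting
into an enrichment web service; enrichment itself is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import AUTOSOMES
from .islands_sharing import IslandSegment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass(frozen=True)
class AnnotationParams:
    flank_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


def _first_attr(feature, keys: Sequence[str], default: str) -> str:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def read_gff(path: str | Path) -> list[GeneRecord]:
    """Extract gene features from a GFF3 or GTF file (1-based inclusive).

    Chromosome names are normalised by stripping a "chr" prefix; records
    on scaffolds outside autosomes 1-18 are dropped with a logged count.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneRecord] = []
    n_dropped = 0
    for feat in db.features_of_type("gene"):
        chrom_txt = feat.seqid.removeprefix("chr")
        try:
            chrom = int(chrom_txt)
        except ValueError:
            n_dropped += 1
            continue
        if chrom not in AUTOSOMES:
            n_dropped += 1
            continue
        gene_id = _first_attr(feat, ("gene_id", "ID"), default=f"{feat.seqid}:{feat.start}")
        gene_name = _first_attr(feat, ("gene_name", "Name"), default=gene_id)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                gene_name=gene_name,
                chromosome=chrom,
                start_bp=feat.start,
                end_bp=feat.end,
                strand=feat.strand or ".",
            )
        )
    if n_dropped:
        logger.info("dropped %d gene records outside autosomes 1-18 from %s", n_dropped, path)
    if not genes:
        warnings.warn(f"no gene features found in {path}")
    return genes


def _gene_trees(genes: Iterable[GeneRecord]) -> dict[int, IntervalTree]:
    trees: dict[int, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    return trees


def _window_of(region, flank_bp: int) -> tuple[int, int, int]:
    """(chrom, start, end) 1-based inclusive window for an island or SNP."""
    if isinstance(region, IslandSegment):
        return region.chromosome, max(1, region.start_bp - flank_bp), region.end_bp + flank_bp
    chrom, pos = region  # hotspot SNP as (chromosome, position)
    return chrom, max(1, pos - flank_bp), pos + flank_bp


def genes_in_regions(
    regions: Sequence,
    genes: Sequence[GeneRecord],
    params: AnnotationParams = AnnotationParams(),
) -> list[list[GeneRecord]]:
    """Genes overlapping each region's flanked window by >= 1 bp.

    Regions are :class:`IslandSegment` objects (island mode) or
    ``(chromosome, position)`` pairs (SNP mode).  Each region's list is
    deduplicated by gene_id and sorted by coordinate.
    """
    trees = _gene_trees(genes)
    out: list[list[GeneRecord]] = []
    for region in regions:
        chrom, lo, hi = _window_of(region, params.flank_bp)
        tree = trees.get(chrom)
        found = {iv.data.gene_id: iv.data for iv in tree.overlap(lo, hi + 1)} if tree else {}
        out.append(sorted(found.values(), key=lambda g: (g.chromosome, g.start_bp, g.gene_id)))
    return out


def annotate_groups(
    islands_by_group: Mapping[str, Sequence[IslandSegment]],
    genes: Sequence[GeneRecord],
    params: AnnotationParams = AnnotationParams(),
) -> tuple[dict[str, list[GeneRecord]], pd.DataFrame]:
    """Per-group deduplicated gene lists plus a per-chromosome tally table.

    The tally has one row per (group, chromosome) with the number of
    islands, hotspot SNPs and distinct genes found there.
    """
    per_group: dict[str, list[GeneRecord]] = {}
    rows = []
    for group, islands in islands_by_group.items():
        hits = genes_in_regions(list(islands), genes, params)
        seen: dict[str, GeneRecord] = {}
        for isl, found in zip(islands, hits):
            for g in found:
                seen.setdefault(g.gene_id, g)
        per_group[group] = sorted(seen.values(), key=lambda g: (g.chromosome, g.start_bp, g.gene_id))
        by_chrom: dict[int, dict] = {}
        for isl, found in zip(islands, hits):
            rec = by_chrom.setdefault(
                isl.chromosome, {"islands": 0, "snps": 0, "genes": set()}
            )
            rec["islands"] += 1
            rec["snps"] += isl.n_hotspot_snps
            rec["genes"].update(g.gene_id for g in found)
        for chrom in sorted(by_chrom):
            rec = by_chrom[chrom]
            rows.append(
                {
                    "group": group,
                    "chrom": chrom,
                    "n_islands": rec["islands"],
                    "n_snps": rec["snps"],
                    "n_genes": len(rec["genes"]),
                }
            )
    tally = pd.DataFrame(rows, columns=["group", "chrom", "n_islands", "n_snps", "n_genes"])
    return per_group, tally


def export_gene_lists(
    per_group_genes: Mapping[str, Sequence[GeneRecord]],
    islands_by_group: Mapping[str, Sequence[IslandSegment]],
    genes: Sequence[GeneRecord],
    out_dir: str | Path,
    params: AnnotationParams = AnnotationParams(),
) -> pd.DataFrame:
    """Write one gene list per group and a combined provenance TSV.

    The per-group files contain one gene name per line (deduplicated);
    the combined TSV records group, chromosome, island coordinates and
    gene for every (island, gene) hit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for group, gene_list in per_group_genes.items():
        path = out_dir / f"genes_{group}.txt"
        names = sorted({g.gene_name for g in gene_list})
        path.write_text("".join(n + "\n" for n in names))
        if not names:
            warnings.warn(f"empty gene list for group {group!r}")
    rows = []
    for group, islands in islands_by_group.items():
        hits = genes_in_regions(list(islands), genes, params)
        for isl, found in zip(islands, hits):
            for g in found:
                rows.append(
                    {
                        "group": group,
                        "chrom": isl.chromosome,
                        "island_start_bp": isl.start_bp,
                        "island_end_bp": isl.end_bp,
                        "gene_id": g.gene_id,
                        "gene_name": g.gene_name,
                    }
                )
    combined = pd.DataFrame(
        rows,
        columns=["group", "chrom", "island_start_bp", "island_end_bp", "gene_id", "gene_name"],
    )
    combined.to_csv(out_dir / "island_gene_annotation.tsv", sep="\t", index=False)
    return combined
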