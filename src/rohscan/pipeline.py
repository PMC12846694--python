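"""End-to-end pipeline: QC -> ROH calling -> statistics -> islands -> annotation.

A single YAML configuration drives every stage with one set of defaults;
all parameters are echoed into a machine-readable run manifest together
with input checksums, so a rerun with the same configuration reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .gene_annotation import AnnotationParams, annotate_groups, export_gene_lists, read_gff
from .genotype_io import (
    read_bed_bim_fam,
    read_ped_map,
    read_sample_table,
    roh_table,
    write_intervals_bed,
)
from .islands_sharing import islands_for_population, islands_frame, venn_segments
from .quality_control import QcParams, apply_qc
from .roh_detection import RohCallParams, call_roh
from .roh_statistics import chromosome_distribution, summarize_panel

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run.

    ``genotype_prefix`` points at either a PED/MAP or a BED/BIM/FAM set
    (``genotype_format`` selects the dialect); ``venn_groups`` names the
    three island sets of the overlap diagram — by default the reference
    breed versus the pooled indigenous and cosmopolitan categories.
    """

    genotype_prefix: str = ""
    genotype_format: str = "ped"  # "ped" or "bed"
    sample_table: str = ""
    gff: str | None = None
    out_dir: str = "results/pipeline"
    reference_breed: str | None = None
    qc: QcParams = field(default_factory=QcParams)
    roh: RohCallParams = field(default_factory=RohCallParams)
    island_top_fraction: float = 0.01
    island_max_gap_bp: int = 500_000
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        for key, typ in (("qc", QcParams), ("roh", RohCallParams), ("annotation", AnnotationParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, writing TSV outputs and a run manifest.

    Stage failures raise :class:`PipelineStageError` naming the stage.
    Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }

    stage = "load"
    try:
        samples = read_sample_table(config.sample_table)
        manifest["inputs"][config.sample_table] = _sha256(Path(config.sample_table))
        if config.genotype_format == "ped":
            geno, markers = read_ped_map(config.genotype_prefix + ".ped", config.genotype_prefix + ".map")
            for ext in (".ped", ".map"):
                manifest["inputs"][config.genotype_prefix + ext] = _sha256(Path(config.genotype_prefix + ext))
        elif config.genotype_format == "bed":
            geno, markers, _ = read_bed_bim_fam(config.genotype_prefix)
            for ext in (".bed", ".bim", ".fam"):
                manifest["inputs"][config.genotype_prefix + ext] = _sha256(Path(config.genotype_prefix + ext))
        else:
            raise ValueError(f"unknown genotype_format {config.genotype_format!r}")

        stage = "qc"
        geno, samples, qc_report = apply_qc(geno, samples, config.qc)
        qc_report.write(out / "qc_report.tsv")
        l_auto = qc_report.l_auto_bp
        manifest["stages"]["qc"] = {"n_samples": geno.n_samples, "n_snps": geno.n_markers, "l_auto_bp": l_auto}

        stage = "call"
        segments = call_roh(geno, params=config.roh)
        breed_of = samples.breed_of()
        roh_table(segments, breed_of).to_csv(out / "roh_segments.hom.tsv", sep="\t", index=False)
        manifest["stages"]["call"] = {"n_segments": len(segments)}

        stage = "stats"
        indiv, breed = summarize_panel(segments, breed_of, l_auto, all_samples=geno.samples)
        indiv.to_csv(out / "individual_summary.tsv", sep="\t", index=False)
        breed.to_csv(out / "breed_summary.tsv", sep="\t", index=False)
        chrom_dist = chromosome_distribution(segments, breed_of)
        chrom_dist.to_csv(out / "chromosome_distribution.tsv", sep="\t")

        stage = "islands"
        frame = samples.frame
        reference = config.reference_breed or sorted(frame["breed"].unique())[0]
        groups = {
            reference: frame.loc[frame["breed"] == reference, "sample"].tolist(),
            "indigenous": frame.loc[
                (frame["category"] == "indigenous") & (frame["breed"] != reference), "sample"
            ].tolist(),
            "cosmopolitan": frame.loc[frame["category"] == "cosmopolitan", "sample"].tolist(),
        }
        groups = {g: members for g, members in groups.items() if members}
        islands_by_group = {
            g: islands_for_population(
                segments, geno.markers, members, g,
                config.island_top_fraction, config.island_max_gap_bp,
            )
            for g, members in groups.items()
        }
        all_islands = [i for isls in islands_by_group.values() for i in isls]
        islands_frame(all_islands).to_csv(out / "islands.tsv", sep="\t", index=False)
        write_intervals_bed(
            ((i.chromosome, i.start_bp, i.end_bp, i.population) for i in all_islands),
            out / "islands.bed",
        )
        manifest["stages"]["islands"] = {g: len(isls) for g, isls in islands_by_group.items()}

        stage = "venn"
        if len(islands_by_group) == 3:
            venn = venn_segments(islands_by_group)
            with open(out / "venn_counts.json", "w") as fh:
                json.dump({"sets": list(venn.set_names), "diagram": venn.diagram,
                           "totals": venn.totals}, fh, indent=2, sort_keys=True)
            manifest["stages"]["venn"] = venn.diagram

        stage = "annotate"
        if config.gff:
            manifest["inputs"][config.gff] = _sha256(Path(config.gff))
            genes = read_gff(config.gff)
            per_group, tally = annotate_groups(islands_by_group, genes, config.annotation)
            tally.to_csv(out / "island_gene_tally.tsv", sep="\t", index=False)
            export_gene_lists(per_group, islands_by_group, genes, out / "gene_lists", config.annotation)
            manifest["stages"]["annotate"] = {g: len(v) for g, v in per_group.items()}
    except Exception as exc:
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
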