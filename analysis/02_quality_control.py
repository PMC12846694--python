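"""Quality-control the panel: marker, sample and breed filters plus L_AUTO.

Applies the standard 50K-array cascade (sample missingness <= 10%,
marker call rate >= 90%, MAF >= 0.05, breeds >= 5 individuals) and
computes the autosomal span L_AUTO that normalises FROH.  Writes the
filtered panel and the QC report under results/qc/.
"""

from pathlib import Path

from rohscan.genotype_io import read_ped_map, read_sample_table, write_ped_map, write_sample_table
from rohscan.quality_control import apply_qc

BASE = Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
ROOT = BASE / "results"


def main() -> None:
    geno, _ = read_ped_map(SCRATCH / "panel" / "panel.ped", SCRATCH / "panel" / "panel.map")
    samples = read_sample_table(SCRATCH / "panel" / "panel.samples.tsv")
    geno, samples, report = apply_qc(geno, samples)

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    qc_scratch = SCRATCH / "qc"
    qc_scratch.mkdir(parents=True, exist_ok=True)
    write_ped_map(geno, qc_scratch / "panel_qc", samples.breed_of())
    write_sample_table(samples, qc_scratch / "panel_qc.samples.tsv")
    report.write(out / "qc_report.tsv")
    print(f"QC: kept {report.n_samples_final}/{report.n_samples_in} individuals, "
          f"{report.n_snps_final}/{report.n_snps_in} markers")
    print(f"removed: {report.samples_removed_missing} samples (missingness), "
          f"{report.snps_removed_callrate} markers (call rate), "
          f"{report.snps_removed_maf} markers (MAF)")
    print(f"L_AUTO = {report.l_auto_bp:,} bp")


if __name__ == "__main__":
    main()
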