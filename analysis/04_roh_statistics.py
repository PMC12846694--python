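"""Descriptive ROH statistics: length classes, FROH, chromosome spread.

Summarises the called segments per individual (count, total length,
FROH = L_ROH / L_AUTO) and per breed (class counts over the 1-5 / 5-10 /
10-20 / 20-40 / >40 Mb bins, mean +/- sd of length, count and FROH), and
tabulates segments per (breed, chromosome).  Also aggregates the bundled
24-breed reference class-count table through the same machinery as a
cross-check of the reporting arithmetic.  Writes results/stats/.
"""

from pathlib import Path

import pandas as pd

from rohscan.genotype_io import read_ped_map, read_sample_table
from rohscan.quality_control import compute_l_auto
from rohscan.roh_detection import RohSegment, call_roh
from rohscan.roh_statistics import (
    aggregate_class_counts,
    chromosome_distribution,
    load_reference_class_counts,
    summarize_panel,
)

BASE = Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
ROOT = BASE / "results"


def main() -> None:
    geno, markers = read_ped_map(SCRATCH / "qc" / "panel_qc.ped", SCRATCH / "qc" / "panel_qc.map")
    samples = read_sample_table(SCRATCH / "qc" / "panel_qc.samples.tsv")
    segments = call_roh(geno)
    l_auto = compute_l_auto(markers)

    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)
    indiv, breed = summarize_panel(segments, samples.breed_of(), l_auto, all_samples=geno.samples)
    indiv.to_csv(out / "individual_summary.tsv", sep="\t", index=False)
    breed.to_csv(out / "breed_summary.tsv", sep="\t", index=False)
    chromosome_distribution(segments, samples.breed_of(), chromosomes=sorted(
        set(markers.chromosomes.tolist()))).to_csv(out / "chromosome_distribution.tsv", sep="\t")

    ref = aggregate_class_counts(load_reference_class_counts())
    ref.to_csv(out / "reference_panel_class_totals.tsv", sep="\t", index=False)

    print(f"L_AUTO = {l_auto:,} bp over {len(set(markers.chromosomes.tolist()))} chromosomes")
    print("per-breed FROH (mean +/- sd):")
    for row in breed.itertuples(index=False):
        print(f"  {row.breed}: FROH {row.mean_f_roh:.4f} +/- {row.sd_f_roh:.4f}, "
              f"{row.mean_n_segments:.1f} segments of {row.mean_length_mb:.2f} Mb on average")
    total = ref["n_segments"].sum()
    print(f"reference 24-breed panel: {total} ROH; class shares "
          + ", ".join(f"{c}: {p}%" for c, p in zip(ref['length_class'], ref['pct'])))


if __name__ == "__main__":
    main()
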