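"""ROH islands and cross-group sharing.

For the reference breed (BR01), the pooled indigenous breeds and the
cosmopolitan group, computes the per-SNP ROH incidence, calls the top-1%
hotspot markers, merges them into island segments, and counts shared
versus exclusive islands across the three groups (the Venn partition).
Islands shared with the reference breed are retained for annotation.
Writes results/islands/.
"""

import json
from pathlib import Path

from rohscan.genotype_io import read_ped_map, read_sample_table, write_intervals_bed
from rohscan.islands_sharing import (
    islands_for_population,
    islands_frame,
    shared_with_reference,
    venn_segments,
)
from rohscan.roh_detection import call_roh

BASE = Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
ROOT = BASE / "results"
REFERENCE = "BR01"


def main() -> None:
    geno, markers = read_ped_map(SCRATCH / "qc" / "panel_qc.ped", SCRATCH / "qc" / "panel_qc.map")
    samples = read_sample_table(SCRATCH / "qc" / "panel_qc.samples.tsv")
    segments = call_roh(geno)

    frame = samples.frame
    groups = {
        REFERENCE: frame.loc[frame["breed"] == REFERENCE, "sample"].tolist(),
        "indigenous": frame.loc[
            (frame["category"] == "indigenous") & (frame["breed"] != REFERENCE), "sample"
        ].tolist(),
        "cosmopolitan": frame.loc[frame["category"] == "cosmopolitan", "sample"].tolist(),
    }
    islands_by_group = {
        g: islands_for_population(segments, markers, members, g)
        for g, members in groups.items()
    }

    out = ROOT / "islands"
    out.mkdir(parents=True, exist_ok=True)
    all_islands = [i for isls in islands_by_group.values() for i in isls]
    islands_frame(all_islands).to_csv(out / "islands.tsv", sep="\t", index=False)
    write_intervals_bed(
        ((i.chromosome, i.start_bp, i.end_bp, i.population) for i in all_islands),
        out / "islands.bed",
    )

    venn = venn_segments(islands_by_group)
    with open(out / "venn_counts.json", "w") as fh:
        json.dump({"sets": list(venn.set_names), "diagram": venn.diagram,
                   "totals": venn.totals}, fh, indent=2, sort_keys=True)

    shared = shared_with_reference(islands_by_group, REFERENCE)
    islands_frame([i for isls in shared.values() for i in isls]).to_csv(
        out / "islands_shared_with_reference.tsv", sep="\t", index=False
    )

    for g, isls in islands_by_group.items():
        print(f"{g}: {len(isls)} islands from top-1% hotspot markers")
    d = venn.diagram
    print(f"venn: exclusive {d['only_A']}/{d['only_B']}/{d['only_C']}, "
          f"pairwise AB={d['AB']} AC={d['AC']} BC={d['BC']}, triple {d['ABC']}")
    for g, isls in shared.items():
        print(f"{g}: {len(isls)} islands shared with {REFERENCE}")


if __name__ == "__main__":
    main()
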