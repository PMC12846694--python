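"""Generate the synthetic multi-breed study panel.

Emulates a medium-density pig genotyping panel: five breeds spanning the
African/American/Asian/European/Cosmopolitan groups, 50 kb marker
spacing, and autozygous tracts implanted at breed-specific rates so that
downstream ROH, FROH, island and annotation stages all have signal.
Writes PED/MAP genotypes, the sample table and the tract ground truth
under results/panel/.
"""

from pathlib import Path

from rohscan.genotype_io import write_ped_map, write_sample_table
from rohscan.synthetic_data import SimParams, TractSpec, simulate_panel

ROOT = Path(__file__).resolve().parents[1]
# raw genotype files are bulky regenerable intermediates -> scratch/
SCRATCH = ROOT / "scratch" / "panel"
OUT = ROOT / "results" / "panel"

PANEL = SimParams(
    n_chromosomes=2,
    markers_per_chromosome=2_000,
    chromosome_length_bp=100_000_000,
    n_breeds=5,
    individuals_per_breed=12,
    missing_rate=0.02,
    seed=11,
    tract_spec=(
        # the reference breed carries the most autozygosity; its first
        # tract sits at a fixed locus shared with BR02 and BR05 so the
        # groups develop overlapping ROH islands
        TractSpec(breed="BR01", carrier_fraction=0.8, tracts_per_carrier=3,
                  length_bp_range=(2_500_000, 40_000_000), at=(1, 20_000_000)),
        TractSpec(breed="BR02", carrier_fraction=0.5, tracts_per_carrier=2,
                  length_bp_range=(2_500_000, 20_000_000), at=(1, 21_000_000)),
        TractSpec(breed="BR03", carrier_fraction=0.5, tracts_per_carrier=2,
                  length_bp_range=(2_500_000, 20_000_000)),
        TractSpec(breed="BR04", carrier_fraction=0.4, tracts_per_carrier=1,
                  length_bp_range=(2_500_000, 15_000_000)),
        # the cosmopolitan breed: fewer but longer runs
        TractSpec(breed="BR05", carrier_fraction=0.6, tracts_per_carrier=2,
                  length_bp_range=(5_000_000, 40_000_000), at=(1, 19_000_000)),
    ),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    geno, markers, samples, truth = simulate_panel(PANEL)
    write_ped_map(geno, SCRATCH / "panel", samples.breed_of())
    write_sample_table(samples, SCRATCH / "panel.samples.tsv")
    truth.tracts.to_csv(OUT / "panel.truth.tsv", sep="\t", index=False)
    print(
        f"panel: {geno.n_samples} individuals x {geno.n_markers} markers "
        f"({PANEL.n_chromosomes} chromosomes, {PANEL.spacing_bp / 1000:.0f} kb spacing)"
    )
    print(f"implanted {len(truth.tracts)} autozygous tracts "
          f"({truth.tracts['length_bp'].min() / 1e6:.1f}-{truth.tracts['length_bp'].max() / 1e6:.1f} Mb)")
    print(f"wrote PED/MAP + sample table to {SCRATCH}; truth to {OUT}")


if __name__ == "__main__":
    main()
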