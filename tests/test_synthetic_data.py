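import numpy as np
import pytest

from rohscan.genotype_io import MISSING
from rohscan.quality_control import compute_l_auto
from rohscan.roh_detection import RohSegment, call_roh
from rohscan.synthetic_data import (
    SimParams,
    TractSpec,
    score_recovery,
    simulate_panel,
)


def small_params(**kw):
    base = dict(
        n_chromosomes=2,
        markers_per_chromosome=800,
        chromosome_length_bp=40_000_000,
        n_breeds=2,
        individuals_per_breed=8,
        seed=3,
    )
    base.update(kw)
    return SimParams(**base)


class TestSimulatePanel:
    def test_tract_markers_forced_homozygous(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", carrier_fraction=1.0, lengths_bp=(2_000_000,)),),
        )
        geno, markers, _, truth = simulate_panel(params)
        idx = {s: i for i, s in enumerate(geno.samples)}
        for row in truth.tracts.itertuples(index=False):
            on_chrom = markers.chromosomes == row.chrom
            inside = on_chrom & (markers.positions >= row.start_bp) & (markers.positions <= row.end_bp)
            calls = geno.calls[idx[row.sample], inside]
            assert np.isin(calls, (0, 2)).all()

    def test_determinism(self):
        params = small_params(
            missing_rate=0.05,
            genotype_error_rate=0.01,
            tract_spec=(TractSpec(breed="BR02", carrier_fraction=0.5, lengths_bp=(3_000_000,)),),
        )
        a = simulate_panel(params)
        b = simulate_panel(params)
        assert np.array_equal(a[0].calls, b[0].calls)
        assert a[3].tracts.equals(b[3].tracts)
        assert a[0].samples == b[0].samples

    def test_background_heterozygosity_matches_hwe(self):
        params = small_params(seed=9)
        geno, _, _, _ = simulate_panel(params)
        rng = np.random.default_rng(params.seed)
        # regenerate the frequency draw the generator made
        freqs = rng.uniform(0.05, 0.5, size=(2, geno.n_markers))
        for bi in range(2):
            rows = slice(bi * 8, (bi + 1) * 8)
            obs = (geno.calls[rows] == 1).sum()
            v = 2 * freqs[bi] * (1 - freqs[bi])
            expect = 8 * v.sum()
            se = np.sqrt(8 * (v * (1 - v)).sum())
            assert abs(obs - expect) <= 3 * se

    def test_tract_longer_than_chromosome_rejected(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", lengths_bp=(50_000_000,)),),
        )
        with pytest.raises(ValueError, match="exceeds chromosome"):
            simulate_panel(params)

    def test_missing_rate_ceiling_enforced(self):
        with pytest.raises(ValueError, match="ceiling"):
            small_params(missing_rate=0.2)

    def test_truth_tracts_within_bounds(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", carrier_fraction=1.0,
                                  tracts_per_carrier=2, length_bp_range=(2_000_000, 10_000_000)),),
        )
        _, _, samples, truth = simulate_panel(params)
        assert (truth.tracts["start_bp"] >= 1).all()
        assert (truth.tracts["end_bp"] <= params.chromosome_length_bp).all()
        assert set(truth.tracts["sample"]) <= set(samples.frame["sample"])


class TestScoreRecovery:
    def test_perfect_calls(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", carrier_fraction=0.5, lengths_bp=(4_000_000,)),),
        )
        _, _, _, truth = simulate_panel(params)
        called = [
            RohSegment(sample=r.sample, chromosome=r.chrom, start_bp=r.start_bp,
                       end_bp=r.end_bp, n_snps=60)
            for r in truth.tracts.itertuples(index=False)
        ]
        score = score_recovery(called, truth)
        assert score.sensitivity == 1.0
        assert score.precision == 1.0
        assert score.boundary_error_bp == 0.0

    def test_no_calls_zero_sensitivity(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", carrier_fraction=0.5, lengths_bp=(4_000_000,)),),
        )
        _, _, _, truth = simulate_panel(params)
        score = score_recovery([], truth)
        assert score.sensitivity == 0.0

    def test_half_overlap_threshold(self):
        params = small_params(
            tract_spec=(TractSpec(breed="BR01", carrier_fraction=1.0, lengths_bp=(8_000_000,)),),
        )
        _, _, _, truth = simulate_panel(params)
        row = truth.tracts.iloc[0]
        # a call covering only a third of the tract misses the 0.5 bar
        called = [
            RohSegment(sample=row["sample"], chromosome=int(row["chrom"]),
                       start_bp=int(row["start_bp"]),
                       end_bp=int(row["start_bp"]) + int(row["length_bp"]) // 3, n_snps=60)
        ]
        sub_truth = type(truth)(
            tracts=truth.tracts.iloc[[0]], markers=truth.markers, samples=truth.samples
        )
        score = score_recovery(called, sub_truth)
        assert score.sensitivity == 0.0


class TestFalsePositiveGuard:
    def test_no_long_calls_without_tracts_at_common_frequencies(self):
        # allele frequencies >= 0.3 keep background heterozygosity high;
        # with no implanted tracts nothing >= 2 Mb may be called
        params = SimParams(
            n_chromosomes=2,
            markers_per_chromosome=2_000,
            chromosome_length_bp=100_000_000,
            n_breeds=2,
            individuals_per_breed=10,
            freq_range=(0.3, 0.5),
            seed=12345,
        )
        geno, _, _, _ = simulate_panel(params)
        segs = call_roh(geno)
        assert not [s for s in segs if s.length_bp >= 2_000_000]


class TestRecoveryExperiment:
    def test_sensitivity_on_noise_free_panel(self):
        params = SimParams(
            seed=77,
            tract_spec=(
                TractSpec(breed="BR01", carrier_fraction=0.6, tracts_per_carrier=2,
                          length_bp_range=(2_000_000, 30_000_000)),
                TractSpec(breed="BR03", carrier_fraction=0.4, tracts_per_carrier=1,
                          length_bp_range=(2_000_000, 30_000_000)),
            ),
        )
        geno, markers, _, truth = simulate_panel(params)
        score = score_recovery(call_roh(geno), truth)
        window_span_bp = 50 * params.spacing_bp
        assert score.sensitivity >= 0.95
        assert score.boundary_error_bp <= window_span_bp

    def test_sensitivity_monotone_in_tract_length(self):
        sens = []
        for length in (1_500_000, 3_000_000, 6_000_000):
            params = small_params(
                seed=21,
                markers_per_chromosome=800,
                chromosome_length_bp=40_000_000,  # 50 kb spacing
                tract_spec=(TractSpec(breed="BR01", carrier_fraction=1.0,
                                      lengths_bp=(length,)),),
            )
            geno, _, _, truth = simulate_panel(params)
            sens.append(score_recovery(call_roh(geno), truth).sensitivity)
        assert sens == sorted(sens)

    def test_froh_recovered_within_two_points(self):
        # carriers planted with tracts totalling 5/10/15% of L_AUTO
        l_auto_target = 2 * 100_000_000
        specs = []
        for breed, frac in (("BR01", 0.05), ("BR02", 0.10), ("BR03", 0.15)):
            total = int(frac * l_auto_target)
            specs.append(TractSpec(breed=breed, carrier_fraction=1.0,
                                   lengths_bp=(total // 2, total // 2)))
        params = SimParams(seed=101, n_breeds=4, individuals_per_breed=5,
                           tract_spec=tuple(specs))
        geno, markers, samples, truth = simulate_panel(params)
        l_auto = compute_l_auto(markers)
        segs = call_roh(geno)
        by_sample = {}
        for s in segs:
            by_sample.setdefault(s.sample, []).append(s)
        for breed, frac in (("BR01", 0.05), ("BR02", 0.10), ("BR03", 0.15)):
            for sample in samples.samples_of_breed(breed):
                planted = truth.tracts_of(sample)["length_bp"].sum()
                called = sum(x.length_bp for x in by_sample.get(sample, []))
                assert called / l_auto == pytest.approx(planted / l_auto, abs=0.02)
                assert planted / l_auto == pytest.approx(frac, abs=0.01)


class TestPlantedHotspotLocus:
    def test_shared_locus_yields_overlapping_islands(self):
        from rohscan.islands_sharing import islands_for_population, venn_segments

        params = SimParams(
            seed=31,
            n_chromosomes=2,
            markers_per_chromosome=1_000,
            chromosome_length_bp=50_000_000,
            n_breeds=3,
            individuals_per_breed=8,
            tract_spec=(
                TractSpec(breed="BR01", carrier_fraction=0.9, lengths_bp=(5_000_000,), at=(1, 10_000_000)),
                TractSpec(breed="BR02", carrier_fraction=0.9, lengths_bp=(5_000_000,), at=(1, 11_000_000)),
                TractSpec(breed="BR03", carrier_fraction=0.9, lengths_bp=(5_000_000,), at=(1, 12_000_000)),
            ),
        )
        geno, markers, samples, truth = simulate_panel(params)
        assert len(truth.planted_hotspots) == 3
        segs = call_roh(geno)
        islands = {
            b: islands_for_population(segs, markers, samples.samples_of_breed(b), b)
            for b in ("BR01", "BR02", "BR03")
        }
        # each breed's top-1% islands sit at the planted locus
        for b, isls in islands.items():
            assert isls, b
            assert any(i.chromosome == 1 and i.start_bp < 17_000_000 and i.end_bp > 10_000_000
                       for i in isls), b
        counts = venn_segments(islands)
        assert counts.diagram["ABC"] >= 1
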