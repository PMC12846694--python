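# Methods

## Scope and data model

The pipeline analyses diploid autosomal SNP-array genotypes for pig
autosomes 1–18. Genotypes are coded 0 (homozygous A1), 1 (heterozygous),
2 (homozygous A2) and −1 (missing); no stage downstream of loading needs
allele identity beyond hom/het/missing, so this biallelic coding is the
whole model. Coordinates are 1-based inclusive throughout (the PLINK
convention); BED interval exports are converted to 0-based half-open on
write. PLINK text (PED/MAP) and PLINK 1 binary (BED/BIM/FAM, SNP-major)
are both read and written. In text input A1 is the first allele
encountered per marker, so a text round trip preserves zygosity exactly
but not necessarily homozygote polarity (the format carries no allele
dictionary); binary round trips are bit-exact because the BIM allele
columns are authoritative.

## Quality control

Filters run in a fixed order: samples with > 10% missing genotypes,
then markers with call rate < 90%, then markers with minor allele
frequency < 0.05 (computed on non-missing calls only), then whole breeds
left with fewer than five individuals. PLINK applies sample and marker
filters jointly, so results can differ from a PLINK run in boundary
cases; the fixed order makes the cascade deterministic and the report
auditable. Individual heterozygosity is inspected, not filtered:
samples beyond 3 standard deviations of the panel mean (configurable)
are flagged only.

`L_AUTO`, the denominator of F_ROH, is the sum over chromosomes of
(last − first marker position + 1) over the markers retained after QC:
the span the panel actually covers, not the assembly length. A
single-marker chromosome contributes 1 bp.

## ROH detection

The scan reproduces the PLINK `--homozyg` heuristic. Per individual and
chromosome, a 50-SNP window slides one SNP at a time; a window is
homozygous when it has ≤ 1 heterozygous and ≤ 2 missing calls. Each
SNP's hit rate is homozygous-windows-containing-it over
windows-containing-it, and SNPs with hit rate ≥ 0.05 are eligible
(0.05 is PLINK v1.9's default window threshold, exposed as a
parameter). Maximal runs of consecutive eligible SNPs are split wherever
the gap between neighbouring markers exceeds 500 kb, then filtered:
length ≥ 1 Mb, ≥ 50 SNPs, and ≤ 100 kb per SNP on the final segment
(not per window). Embedded heterozygous SNPs may remain inside a
segment when their hit rate passes, as in PLINK without a per-segment
heterozygote cap. Chromosomes with fewer markers than the window size
are scanned with a single whole-chromosome window — the degenerate case
is defined here rather than left unspecified.

The minimum SNPs per final segment is set to 50, matching the window
size, which is common practice for 50K-density arrays (PLINK's separate
`--homozyg-snp` default would be 100); it is configurable.

A brute-force oracle (`call_roh_bruteforce`) re-implements the identical
contract by direct enumeration with no shared code, and the test suite
asserts segment-set equality on hundreds of randomized instances across
the het/missing/gap/length parameter grid.

## Statistics

F_ROH = L_ROH / L_AUTO per individual; zero segments give F_ROH = 0, and
removing a segment of length ℓ lowers F_ROH by exactly ℓ / L_AUTO.
Segments fall into five length classes — 1–5, 5–10, 10–20, 20–40,
> 40 Mb — with half-open bins closed on the left, so a segment of
exactly 5 Mb is counted in 5–10 (shared endpoints in the conventional
labels are ambiguous; upward assignment is fixed and tested). Breed
summaries report mean ± sample standard deviation (n − 1) and min–max
ranges for per-individual mean length, segment count and F_ROH; a breed
of one individual reports sd 0 with a degeneracy flag. Per-individual
mean lengths are averaged over individuals carrying at least one
segment. The package also bundles a published 24-breed class-count
table as a reporting fixture: aggregating it through the same machinery
must reproduce its printed class totals (717 / 4543 / 2527 / 714 / 79 of
8580) and percentage shares, which pins the reporting arithmetic. One
printed share (10–20 Mb) appears truncated rather than rounded in its
source (2527/8580 = 29.45% vs 29.4 printed), so the check allows one
unit in the last printed decimal.

## Islands and sharing

Per population, each marker's incidence is the fraction of individuals
with an ROH covering it (an individual counts at most once per marker
regardless of segment multiplicity; overlapping segments within one
individual are rejected as an upstream invariant violation). Hotspots
are markers at or above the (1 − 0.01) quantile of the incidence
spectrum, ties included — the hotspot set is never an arbitrary subset
of equally frequent markers — and zero-incidence markers never qualify.
The top-1% cut is taken within each population, not on a pooled
spectrum. Runs of hotspot markers consecutive in map order with gaps
≤ 500 kb (reusing the ROH gap bound; no separate island-merge rule is
defined) become island segments; an isolated hotspot yields a
zero-length island that is retained.

Sharing between groups means ≥ 1 bp of coordinate overlap (exposed as a
parameter; no reciprocal-overlap fraction is imposed). In the three-set
Venn partition each group's islands are assigned to exactly one of four
regions (exclusive, two pairwise, triple) by which other groups they
overlap; because overlap counts are asymmetric at the segment level,
the seven diagram numbers are reported from the first-listed group of
each region and the per-group partitions are preserved alongside. For
reference-based sharing, islands of every other population overlapping
any island of the reference population are retained with their full
spans for annotation.

## Gene annotation

Gene features are read from GFF3 or GTF (via gffutils, in-memory);
chromosome names are normalised by stripping a `chr` prefix and
non-autosomal scaffolds are dropped with a count. Two modes implement
the two natural region definitions: each hotspot SNP contributes a
± 50 kb window (a 100 kb region), or each island contributes its span
± 50 kb; a gene is reported on ≥ 1 bp overlap, strand ignored (windows
are symmetric and SNPs strandless). Lists are deduplicated per region
and per group; exports are one plain-text gene list per group plus a
combined provenance TSV (group, chromosome, island coordinates, gene).
Downstream GO/KEGG enrichment depends on external web services and live
database releases and is deliberately out of scope — the contract ends
at reproducible gene lists.

## Synthetic panels

The generator emulates a multi-breed 50K-style panel: evenly spaced
markers (default 2 chromosomes × 2,000 markers at 50 kb), per-breed
allele frequencies drawn uniformly from [0.05, 0.5], background
genotypes sampled under Hardy–Weinberg equilibrium, ≤ 10% missingness,
and optional symmetric hom↔het genotype errors. Autozygous tracts are
implanted by drawing one founder haplotype and doubling it, forcing
every marker in the tract homozygous; noise is applied after
implantation and the recorded truth is pre-noise. Tracts of one carrier
are kept ≥ 2 Mb apart so recovery scoring stays unambiguous, and a
tract may be pinned to a fixed locus to create hotspot regions shared
across breeds. A fixed seed makes output bit-reproducible.

Background linkage disequilibrium is *not* simulated: markers are
independent given their frequencies. Implanted tracts are therefore the
only source of long homozygosity, which is exactly what recovery
experiments need, but the short-ROH background of real arrays (where LD
creates chance runs) is not reproduced — passing tests demonstrate the
machinery, not real-data short-ROH calibration.

Recovery scoring matches called segments to truth tracts of the same
individual and chromosome at ≥ 0.5 reciprocal overlap; sensitivity is
the fraction of tracts recovered, precision the fraction of calls
matching any tract, and boundary error the mean |called − true|
endpoint offset over recovered tracts. On noise-free 50 kb-spacing
panels the caller recovers essentially all tracts ≥ 2.5 Mb with
boundary errors around 100–150 kb (hit-rate eligibility extends a few
markers past each tract edge before background heterozygosity
extinguishes it, and trims a couple of markers at the very edge).
Tracts between 2 and 2.5 Mb carry only 40–50 markers at this density —
below the 50-SNP segment floor — and are recovered only when edge
extension lifts them over it, so sensitivity in that marginal class is
seed-dependent; F_ROH recovery for planted fractions of 5/10/15% of
L_AUTO is accurate to a few thousandths.

## Pipeline and determinism

`run_pipeline` chains QC → calling → statistics → islands → Venn →
annotation from one YAML configuration whose defaults are the preset
above, and writes a JSON manifest with all parameters, input SHA-256
checksums and stage tallies. All randomness sits in the generator and
is seed-controlled; the analysis stages are deterministic, so reruns on
the same inputs produce byte-identical tabular outputs (asserted in the
test suite). Stage failures abort with the stage name and a non-zero
exit status.

## Problem sizes

Tests and the acceptance script run desk-scale configurations — panels
up to 2 × 2,000 markers and 60 individuals, 200 randomized
oracle-comparison instances of ≤ 500 SNPs × ≤ 20 individuals — chosen
so the whole suite completes in seconds while still exercising every
code path at realistic marker density. The implementation itself is
vectorised per individual × chromosome and handles 50K-marker,
500-sample panels comfortably.

## Known limitations

- No LD, recombination maps, coalescent ancestry or admixture in the
  generator; tract implantation is the only demographic signal.
- PED text round trips preserve zygosity but not homozygote polarity
  (format limitation; irrelevant downstream).
- Filter-order boundary cases can differ from PLINK's joint filtering.
- Enrichment statistics are out of scope; exports are formatted for
  pasting into external services.
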