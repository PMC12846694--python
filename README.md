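# rohscan

Runs-of-homozygosity (ROH) analysis for multi-breed SNP-array panels:
genotype quality control, PLINK-style sliding-window ROH detection,
genomic inbreeding (F_ROH), ROH length-class statistics, top-1% ROH
islands, cross-population island sharing, and gene annotation of shared
segments — plus a synthetic-genotype generator with implanted autozygous
tracts so the whole pipeline is testable without restricted study data.

The package is aimed at livestock population genomicists working with
medium-density arrays (for example a porcine 50K chip over autosomes
1–18) who want a scripted, reproducible version of the standard
PLINK-plus-R ROH workflow with ground-truth validation built in.

## The method

An ROH is a contiguous stretch of homozygous genotypes; long runs signal
recent common ancestry of the two haplotypes. Detection follows the
sliding-window heuristic: a window of 50 consecutive SNPs slides one SNP
at a time; a window is *homozygous* if it contains ≤ 1 heterozygous and
≤ 2 missing calls; each SNP is scored by the fraction of covering
windows that are homozygous and becomes eligible at ≥ 0.05; maximal runs
of eligible SNPs — split at inter-marker gaps > 500 kb — are kept as
segments if they span ≥ 1 Mb, contain ≥ 50 SNPs and average ≤ 100 kb per
SNP. Segments are binned into 1–5, 5–10, 10–20, 20–40 and > 40 Mb
classes.

Genomic inbreeding is

```
F_ROH = L_ROH / L_AUTO
```

where `L_ROH` is an individual's summed segment length and `L_AUTO` the
summed per-chromosome physical span of the marker panel. Per-population
ROH *islands* are the top 1% of SNPs in the per-SNP ROH-incidence
spectrum, merged into segments; islands are compared across populations
by coordinate intersection (≥ 1 bp overlap), and genes are pulled from a
local GFF3/GTF within ± 50 kb of each island.

Every stage has an independent check: the window scan is verified
against a brute-force enumeration oracle, and the generator records
implanted tract coordinates so sensitivity, precision, boundary error
and F_ROH recovery are measured against known truth.

## Worked example

The `analysis/` scripts run the full study on a synthetic five-breed
panel (2 chromosomes × 2,000 markers at 50 kb spacing, 60 individuals,
2% missingness, 73 implanted tracts of 2.7–39.7 Mb, one locus shared
across three breeds):

```bash
python analysis/01_simulate_panel.py
python analysis/02_quality_control.py
python analysis/03_call_roh.py
python analysis/04_roh_statistics.py
python analysis/05_islands_sharing.py
python analysis/06_gene_annotation.py
```

which prints, among other things:

```
QC: kept 60/60 individuals, 4000/4000 markers
L_AUTO = 199,900,002 bp
called 80 ROH segments in 60 individuals
recovery vs truth: sensitivity 0.973, precision 0.887, mean boundary error 583 kb
  BR01: FROH 0.2835 +/- 0.1522, 3.0 segments of 19.10 Mb on average
  BR04: FROH 0.0188 +/- 0.0257, 0.4 segments of 9.01 Mb on average
venn: exclusive 0/0/2, pairwise AB=0 AC=0 BC=0, triple 1
indigenous: 1 islands shared with BR01
```

Reading: the caller recovers 97% of implanted tracts with endpoint
offsets well under one window span; breeds implanted with more
autozygosity (BR01) show proportionally higher F_ROH than lightly
implanted ones (BR04); and the tract locus shared by three breeds
surfaces as one island common to all three groups in the Venn
partition. Tables land under `results/`, bulky regenerable genotype
files under `scratch/`.

The same stages are available as a CLI (`rohscan simulate | qc | call |
stats | islands | annotate | run`); `rohscan run --config cfg.yaml`
executes everything from one YAML file and writes a run manifest with
parameters and input checksums.

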