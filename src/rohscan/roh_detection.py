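"""Sliding-window runs-of-homozygosity detection.

The scan follows the PLINK v1.9 ``--homozyg`` heuristic: a fixed-size
window of ``window_snps`` consecutive markers slides one marker at a time
along each chromosome of each individual; a window counts as homozygous
if it contains at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls.  Each marker is scored by the
fraction of windows containing it that are homozygous, and markers whose
score reaches ``window_hit_threshold`` become eligible.  Maximal runs of
consecutive eligible markers — split wherever the physical gap between
neighbours exceeds ``max_gap_bp`` — are candidate segments, retained when
they satisfy the minimum length, minimum marker count and marker-density
constraints.

Embedded heterozygous markers can remain inside a segment when their hit
rate passes, exactly as in PLINK (no per-segment heterozygote cap is
applied).  Chromosomes with fewer markers than the window size are scanned
with a single window spanning the whole chromosome.

:func:`call_roh` is the vectorised production path;
:func:`call_roh_bruteforce` re-implements the identical contract with
plain loops and shares no code with it, serving as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class RohCallParams:
    """ROH scan thresholds (defaults: the standard 50K-array preset).

    window_snps
        Markers per sliding window (50).
    window_max_het, window_max_missing
        Heterozygous (1) and missing (2) calls tolerated per window.
    min_length_bp
        Minimum segment length, 1 Mb.
    min_density_bp_per_snp
        Maximum bp per marker inside a segment (one SNP per 100 kb).
    max_gap_bp
        Maximum gap between consecutive markers of one segment (500 kb).
    window_hit_threshold
        Minimum fraction of homozygous windows covering a marker (0.05,
        the PLINK default).
    min_segment_snps
        Minimum markers per final segment (50).
    """

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 2
    min_length_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000
    max_gap_bp: int = 500_000
    window_hit_threshold: float = 0.05
    min_segment_snps: int = 50

    def __post_init__(self) -> None:
        if self.window_max_het >= self.window_snps:
            raise ValueError("window_max_het must be < window_snps")
        if min(self.min_length_bp, self.min_density_bp_per_snp, self.max_gap_bp) <= 0:
            raise ValueError("length/density/gap parameters must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run: 1-based inclusive bp span on one chromosome."""

    sample: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    first_snp: str = "."
    last_snp: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def sort_key(self) -> tuple:
        return (self.sample, self.chromosome, self.start_bp)

    def span_key(self) -> tuple:
        return (self.sample, self.chromosome, self.start_bp, self.end_bp, self.n_snps)


def _eligible_snps_fast(calls: np.ndarray, params: RohCallParams) -> np.ndarray:
    """Boolean eligibility per marker of one individual on one chromosome."""
    n = len(calls)
    w = params.window_snps
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    if n < w:
        ok = het.sum() <= params.window_max_het and mis.sum() <= params.window_max_missing
        return np.full(n, ok, dtype=bool)
    # window sums via cumulative sums; window i covers markers [i, i+w)
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(mis)))
    het_w = ch[w:] - ch[:-w]
    mis_w = cm[w:] - cm[:-w]
    win_ok = ((het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)).astype(np.int64)
    n_win = n - w + 1
    # windows covering marker j: indices [max(0, j-w+1), min(j, n_win-1)]
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    cok = np.concatenate(([0], np.cumsum(win_ok)))
    hits = cok[hi + 1] - cok[lo]
    total = hi - lo + 1
    return hits / total >= params.window_hit_threshold


def _runs_to_segments(
    eligible: np.ndarray,
    positions: np.ndarray,
    snp_ids: tuple[str, ...],
    sample: str,
    chromosome: int,
    params: RohCallParams,
) -> list[RohSegment]:
    """Split eligible runs at large gaps and apply segment-level filters."""
    out: list[RohSegment] = []
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return out
    # break runs where markers are non-consecutive or the physical gap is too big
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(positions[idx]) > params.max_gap_bp)
    )
    for run in np.split(idx, breaks + 1):
        start, end = int(positions[run[0]]), int(positions[run[-1]])
        n_snps = len(run)
        length = end - start + 1
        if length < params.min_length_bp or n_snps < params.min_segment_snps:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        out.append(
            RohSegment(
                sample=sample,
                chromosome=chromosome,
                start_bp=start,
                end_bp=end,
                n_snps=n_snps,
                first_snp=snp_ids[run[0]],
                last_snp=snp_ids[run[-1]],
            )
        )
    return out


def call_roh(
    geno: GenotypeMatrix, markers: MarkerMap | None = None, params: RohCallParams = RohCallParams()
) -> list[RohSegment]:
    """Call ROH for every individual; output sorted by (sample, chrom, start)."""
    markers = markers if markers is not None else geno.markers
    if markers is not geno.markers and not np.array_equal(
        markers.positions, geno.markers.positions
    ):
        raise ValueError("marker map does not match the genotype matrix")
    segments: list[RohSegment] = []
    slices = markers.chromosome_slices()
    for i, sample in enumerate(geno.samples):
        row = geno.calls[i]
        for chrom, sl in slices.items():
            eligible = _eligible_snps_fast(row[sl], params)
            segments.extend(
                _runs_to_segments(
                    eligible,
                    markers.positions[sl],
                    markers.ids[sl],
                    sample,
                    chrom,
                    params,
                )
            )
    segments.sort(key=RohSegment.sort_key)
    return segments


# ---------------------------------------------------------------------------
# Brute-force oracle — same contract, no shared code with the fast path
# ---------------------------------------------------------------------------

_BRUTEFORCE_MAX_CELLS = 2_000 * 50


def call_roh_bruteforce(
    geno: GenotypeMatrix, markers: MarkerMap | None = None, params: RohCallParams = RohCallParams()
) -> list[RohSegment]:
    """Direct enumeration of every window and candidate run (test oracle).

    Refuses instances larger than ~2,000 markers x 50 individuals.
    """
    markers = markers if markers is not None else geno.markers
    if geno.n_markers * geno.n_samples > _BRUTEFORCE_MAX_CELLS * 50:
        raise ValueError("instance too large for the brute-force oracle")
    if geno.n_markers > 2_000 or geno.n_samples > 50:
        raise ValueError("instance too large for the brute-force oracle")

    segments: list[RohSegment] = []
    chroms = sorted({int(c) for c in markers.chromosomes})
    for i, sample in enumerate(geno.samples):
        for chrom in chroms:
            idx = [j for j in range(len(markers)) if markers.chromosomes[j] == chrom]
            calls = [int(geno.calls[i, j]) for j in idx]
            pos = [int(markers.positions[j]) for j in idx]
            ids = [markers.ids[j] for j in idx]
            n = len(calls)
            w = params.window_snps

            # enumerate windows
            if n < w:
                windows = [(0, n - 1)]
            else:
                windows = [(s, s + w - 1) for s in range(n - w + 1)]
            window_ok = []
            for s, e in windows:
                het = sum(1 for c in calls[s : e + 1] if c == 1)
                mis = sum(1 for c in calls[s : e + 1] if c == MISSING)
                window_ok.append(het <= params.window_max_het and mis <= params.window_max_missing)

            # per-marker hit rate
            eligible = []
            for j in range(n):
                covering = [k for k, (s, e) in enumerate(windows) if s <= j <= e]
                hits = sum(1 for k in covering if window_ok[k])
                eligible.append(hits / len(covering) >= params.window_hit_threshold)

            # candidate runs: consecutive eligible markers, split at big gaps
            run: list[int] = []
            runs: list[list[int]] = []
            for j in range(n):
                if not eligible[j]:
                    if run:
                        runs.append(run)
                        run = []
                    continue
                if run and pos[j] - pos[run[-1]] > params.max_gap_bp:
                    runs.append(run)
                    run = []
                run.append(j)
            if run:
                runs.append(run)

            for r in runs:
                start, end = pos[r[0]], pos[r[-1]]
                length = end - start + 1
                if length < params.min_length_bp:
                    continue
                if len(r) < params.min_segment_snps:
                    continue
                if length / len(r) > params.min_density_bp_per_snp:
                    continue
                segments.append(
                    RohSegment(
                        sample=sample,
                        chromosome=chrom,
                        start_bp=start,
                        end_bp=end,
                        n_snps=len(r),
                        first_snp=ids[r[0]],
                        last_snp=ids[r[-1]],
                    )
                )
    segments.sort(key=RohSegment.sort_key)
    return segments
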