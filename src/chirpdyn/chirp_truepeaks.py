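"""Dual-probe ChIRP-seq "true peak" pipeline.

ChIRP retrieves an lncRNA's chromatin with two independent ("even" and
"odd") tiling-probe pools; a genuine binding site must appear with the same
shape in both. The pipeline here mirrors that logic:

1. call candidate peaks per probe lane against the input lane with a
   sliding-window local-Poisson test (a simplified MACS-style caller);
2. pair even/odd peaks that agree in position and summit ("raw peaks");
3. score each raw peak's even/odd concordance (coverage, fold enrichment
   over input, per-base Pearson r) in a window of +/- 2 kb around the
   summit or the peak width, whichever is narrower;
4. keep raw peaks with average coverage > 1.5, fold enrichment > 2 and
   Pearson r > 0.3 as "true peaks" (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    combine_tracks,
)
from .rank_stats import mannwhitney_u

LOG10 = math.log(10.0)

ANNOTATION_CATEGORIES = (
    "promoter<=1kb",
    "promoter1-2kb",
    "promoter2-3kb",
    "exon",
    "intron",
    "downstream<=3kb",
    "distal_intergenic",
)


@dataclass(frozen=True)
class PeakCallParams:
    """Sliding-window Poisson caller parameters (MACS-inspired defaults)."""

    p_cutoff: float = 1e-5
    window: int = 300
    step: int = 50
    local_lambda_span: int = 10_000
    min_gap: int = 100
    min_len: int = 150
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must be in (0, 1)")
        if not (self.window >= self.step > 0):
            raise ValueError("need window >= step > 0")


@dataclass(frozen=True)
class RawPeak:
    """An even/odd-concordant peak pair (union interval, combined summit)."""

    interval: GenomicInterval
    summit: int
    even_peak: Peak
    odd_peak: Peak

    def __post_init__(self) -> None:
        if self.even_peak.interval.overlap(self.odd_peak.interval) <= 0:
            raise ValueError("even and odd peaks must overlap")


@dataclass(frozen=True)
class ConcordanceScore:
    avg_coverage: float
    fold_enrichment: float
    pearson_r: float
    window: GenomicInterval

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.pearson_r <= 1.0 + 1e-9):
            raise ValueError("pearson_r out of [-1, 1]")
        if self.avg_coverage < 0:
            raise ValueError("avg_coverage must be >= 0")


@dataclass(frozen=True)
class TruePeakFilter:
    min_avg_coverage: float = 1.5
    min_fold_enrichment: float = 2.0
    min_pearson: float = 0.3
    window_halfwidth: int = 2000
    fe_pseudocount: float = 0.25  # rpm, both numerator and denominator

    def __post_init__(self) -> None:
        for v in (self.min_avg_coverage, self.min_fold_enrichment, self.min_pearson):
            if v <= 0:
                raise ValueError("thresholds must be > 0")

    def passes(self, score: ConcordanceScore) -> bool:
        return (
            score.avg_coverage > self.min_avg_coverage
            and score.fold_enrichment > self.min_fold_enrichment
            and score.pearson_r > self.min_pearson
        )


@dataclass
class TruePeak:
    raw: RawPeak
    score: ConcordanceScore
    signal_rpkm: float | None = None

    @property
    def interval(self) -> GenomicInterval:
        return self.raw.interval

    @property
    def summit(self) -> int:
        return self.raw.summit


@dataclass(frozen=True)
class PeakAnnotation:
    peak_name: str
    summit: int
    chrom: str
    category: str
    target_gene_id: str | None = None


# ---------------------------------------------------------------------------
# candidate peak calling


def call_candidate_peaks(
    track: CoverageTrack,
    input_track: CoverageTrack,
    params: PeakCallParams = PeakCallParams(),
    lane: str = "combined",
) -> list[Peak]:
    """Sliding-window Poisson peak caller against an input control.

    Windows of ``params.window`` bases stepped by ``params.step`` are scored
    with P(X >= obs | lambda) where lambda is the largest of the genome-wide
    input expectation, a local expectation over ``local_lambda_span`` bases,
    and ``pseudocount`` — the input scaled by the library-size ratio.
    Significant windows (p < p_cutoff) are merged when separated by at most
    ``min_gap`` bases and merged peaks shorter than ``min_len`` are dropped.
    """
    if track.norm != "raw" or input_track.norm != "raw":
        raise ValueError("peak calling requires raw tracks")
    if set(track.data) != set(input_track.data):
        raise ValueError("signal and input tracks have different chromosome sets")
    if not track.data or all(len(a) == 0 for a in track.data.values()):
        raise ValueError("zero-length track")
    if track.library_size <= 0 or input_track.library_size <= 0:
        raise ValueError("library sizes must be > 0")

    ratio = track.library_size / input_track.library_size
    lambda_bg_per_base = (
        input_track.total_signal() / input_track.genome_length() * ratio
    )

    peaks: list[Peak] = []
    for chrom in track.chroms:
        clen = track.chrom_sizes[chrom]
        sig = track.values(chrom, 0, clen).astype(float)
        ctl = input_track.values(chrom, 0, clen).astype(float)
        if clen < params.window:
            continue
        csum_sig = np.concatenate(([0.0], np.cumsum(sig)))
        csum_ctl = np.concatenate(([0.0], np.cumsum(ctl)))

        starts = np.arange(0, clen - params.window + 1, params.step)
        if starts[-1] != clen - params.window:
            starts = np.append(starts, clen - params.window)
        ends = starts + params.window
        obs = np.round(csum_sig[ends] - csum_sig[starts])

        centers = (starts + ends) // 2
        half = params.local_lambda_span // 2
        lo = np.clip(centers - half, 0, clen)
        hi = np.clip(centers + half, 0, clen)
        local_mean = (csum_ctl[hi] - csum_ctl[lo]) / np.maximum(hi - lo, 1)
        lam_local = local_mean * params.window * ratio
        lam = np.maximum.reduce(
            [
                np.full_like(lam_local, lambda_bg_per_base * params.window),
                lam_local,
                np.full_like(lam_local, params.pseudocount),
            ]
        )
        logsf = stats.poisson.logsf(obs - 1, lam)  # P(X >= obs)
        sig_mask = logsf < math.log(params.p_cutoff)
        if not sig_mask.any():
            continue

        # merge significant windows into peak intervals
        idx = np.flatnonzero(sig_mask)
        merged: list[list[int]] = []  # [start, end, best_window_index]
        for i in idx:
            s, e = int(starts[i]), int(ends[i])
            if merged and s <= merged[-1][1] + params.min_gap:
                merged[-1][1] = max(merged[-1][1], e)
                if logsf[i] < logsf[merged[-1][2]]:
                    merged[-1][2] = i
            else:
                merged.append([s, e, i])

        for s, e, best in merged:
            if e - s < params.min_len:
                continue
            summit = s + int(np.argmax(sig[s:e]))  # leftmost argmax
            # cap -log10 p where the survival function underflows
            score = min(-logsf[best] / LOG10, 1e4)
            fe = float(obs[best] / lam[best])
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), summit, float(score), fe, lane)
            )
    return peaks


# ---------------------------------------------------------------------------
# raw-peak matching


def match_raw_peaks(
    even: list[Peak],
    odd: list[Peak],
    combined: CoverageTrack,
    min_recip_overlap: float = 0.5,
    max_summit_dist: int = 500,
) -> list[RawPeak]:
    """Pair even/odd peaks that share position and summit.

    Candidate pairs need reciprocal overlap >= ``min_recip_overlap`` and
    summit distance <= ``max_summit_dist``; a greedy one-to-one assignment
    by descending overlap (ties: smaller summit distance, then leftmost)
    makes the matching deterministic.
    """
    pairs = []
    for i, pe in enumerate(even):
        for j, po in enumerate(odd):
            ov = pe.interval.overlap(po.interval)
            if ov <= 0:
                continue
            recip = min(ov / len(pe.interval), ov / len(po.interval))
            sd = abs(pe.summit - po.summit)
            if recip >= min_recip_overlap and sd <= max_summit_dist:
                pairs.append((recip, sd, pe.interval.start, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))

    used_even: set[int] = set()
    used_odd: set[int] = set()
    out = []
    for _, _, _, i, j in pairs:
        if i in used_even or j in used_odd:
            continue
        used_even.add(i)
        used_odd.add(j)
        pe, po = even[i], odd[j]
        start = min(pe.interval.start, po.interval.start)
        end = max(pe.interval.end, po.interval.end)
        chrom = pe.interval.chrom
        vals = combined.values(chrom, start, end)
        summit = start + int(np.argmax(vals))
        out.append(
            RawPeak(GenomicInterval(chrom, start, end), summit, pe, po)
        )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


# ---------------------------------------------------------------------------
# concordance scoring and filtering


def _rpm_factor(track: CoverageTrack) -> float:
    if track.norm == "rpm":
        return 1.0
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0")
    return 1e6 / track.library_size


def scoring_window(raw: RawPeak, halfwidth: int, chrom_len: int) -> GenomicInterval:
    """+/- halfwidth around the summit or the peak width, whichever is
    narrower, clipped to the chromosome."""
    if len(raw.interval) <= 2 * halfwidth:
        iv = raw.interval
        return iv
    start = max(0, raw.summit - halfwidth)
    end = min(chrom_len, raw.summit + halfwidth)
    return GenomicInterval(raw.interval.chrom, start, end)


def score_concordance(
    raw: RawPeak,
    even: CoverageTrack,
    odd: CoverageTrack,
    combined: CoverageTrack,
    input_track: CoverageTrack,
    filt: TruePeakFilter = TruePeakFilter(),
) -> ConcordanceScore:
    """Coverage / enrichment / even-odd Pearson over the scoring window.

    All terms are computed on rpm-scaled per-base vectors, so library-size
    differences between lanes cancel. A constant even or odd vector has
    undefined correlation and is scored r = 0 (it then fails the filter).
    """
    chrom = raw.interval.chrom
    window = scoring_window(raw, filt.window_halfwidth, combined.chrom_sizes[chrom])
    if len(window) < 2:
        raise ValueError("scoring window shorter than 2 bases")

    comb = combined.values(chrom, window.start, window.end) * _rpm_factor(combined)
    inp = input_track.values(chrom, window.start, window.end) * _rpm_factor(
        input_track
    )
    ev = even.values(chrom, window.start, window.end) * _rpm_factor(even)
    od = odd.values(chrom, window.start, window.end) * _rpm_factor(odd)

    avg_cov = float(np.mean(comb))
    eps = filt.fe_pseudocount
    fe = (avg_cov + eps) / (float(np.mean(inp)) + eps)
    if np.ptp(ev) == 0 or np.ptp(od) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(ev, od)[0, 1])
    return ConcordanceScore(avg_cov, float(fe), r, window)


def filter_true_peaks(
    candidates: list[tuple[RawPeak, ConcordanceScore]],
    filt: TruePeakFilter = TruePeakFilter(),
) -> list[TruePeak]:
    """Keep raw peaks passing all three thresholds strictly, sorted by
    coordinate."""
    kept = [TruePeak(raw, sc) for raw, sc in candidates if filt.passes(sc)]
    kept.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return kept


def quantify_peak_rpkm(track: CoverageTrack, peaks) -> np.ndarray:
    """Peak signal as reads-per-kilobase-per-million.

    RPKM = reads_in_peak * 1e9 / (peak_length * library_size); the value is
    also attached to TruePeak.signal_rpkm where the peak objects allow it.
    """
    if track.norm != "raw":
        raise ValueError("RPKM needs a raw track with a library size")
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0")
    out = np.empty(len(peaks))
    for i, p in enumerate(peaks):
        iv = p.interval
        if len(iv) == 0:
            raise ValueError("zero-length peak")
        reads = float(np.sum(track.values(iv.chrom, iv.start, iv.end)))
        out[i] = reads * 1e9 / (len(iv) * track.library_size)
        if isinstance(p, TruePeak):
            p.signal_rpkm = float(out[i])
    return out


def compare_peak_signal(rpkm_a, rpkm_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two peak-signal samples."""
    return mannwhitney_u(rpkm_a, rpkm_b)


# ---------------------------------------------------------------------------
# annotation and gene-set logic


def _classify_summit(
    summit: int, chrom: str, genes: list[GeneModel]
) -> tuple[str, str | None]:
    same = [g for g in genes if g.chrom == chrom]
    # promoter bands by distance to the nearest TSS (both directions)
    best_gene, best_d = None, None
    for g in same:
        d = abs(summit - g.tss)
        if best_d is None or d < best_d:
            best_gene, best_d = g, d
    if best_d is not None:
        if best_d <= 1000:
            return "promoter<=1kb", best_gene.gene_id
        if best_d <= 2000:
            return "promoter1-2kb", best_gene.gene_id
        if best_d <= 3000:
            return "promoter2-3kb", best_gene.gene_id
    for g in same:
        for ex in g.exons:
            if ex.start <= summit < ex.end:
                return "exon", g.gene_id
    for g in same:
        if g.interval.start <= summit < g.interval.end:
            return "intron", g.gene_id
    for g in same:
        if g.strand == "+" and g.tts < summit <= g.tts + 3000:
            return "downstream<=3kb", g.gene_id
        if g.strand == "-" and g.tts - 3000 <= summit < g.tts:
            return "downstream<=3kb", g.gene_id
    return "distal_intergenic", None


def annotate_peaks(
    peaks, genes: list[GeneModel]
) -> tuple[list[PeakAnnotation], dict[str, float]]:
    """Classify each peak summit into exactly one genomic category.

    Priority: promoter bands (distance from TSS, strand-agnostic within the
    band) > exon > intron > downstream<=3kb > distal intergenic. The second
    return value is the fraction of peaks per category (sums to 1).
    """
    annos = []
    counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    for i, p in enumerate(peaks):
        category, gid = _classify_summit(p.summit, p.interval.chrom, genes)
        name = p.interval.name or f"peak_{i + 1}"
        annos.append(PeakAnnotation(name, p.summit, p.interval.chrom, category, gid))
        counts[category] += 1
    n = max(1, len(peaks))
    fractions = {c: counts[c] / n for c in ANNOTATION_CATEGORIES}
    return annos, fractions


def assign_target_genes(
    true_peaks, genes: list[GeneModel], upstream_ext: int = 2000
) -> set[str]:
    """Genes whose body (extended ``upstream_ext`` bases upstream of the
    TSS) is overlapped by at least one true peak."""
    targets: set[str] = set()
    for g in genes:
        if g.strand == "+":
            start = max(0, g.interval.start - upstream_ext)
            end = g.interval.end
        else:
            start = g.interval.start
            end = g.interval.end + upstream_ext
        region = GenomicInterval(g.chrom, start, end)
        for p in true_peaks:
            if p.interval.overlap(region) > 0:
                targets.add(g.gene_id)
                break
    return targets


def replicate_gene_sets(
    targets_rep1: set[str], targets_rep2: set[str], targets_control: set[str]
) -> dict:
    """Replicate-common and control-subtracted ("gain") target-gene sets,
    with all seven exclusive Venn-region counts."""
    r1, r2, c = set(targets_rep1), set(targets_rep2), set(targets_control)
    common = r1 & r2
    gain = common - c
    venn = {
        "rep1_only": len(r1 - r2 - c),
        "rep2_only": len(r2 - r1 - c),
        "control_only": len(c - r1 - r2),
        "rep1_rep2_only": len((r1 & r2) - c),
        "rep1_control_only": len((r1 & c) - r2),
        "rep2_control_only": len((r2 & c) - r1),
        "all_three": len(r1 & r2 & c),
    }
    return {"common": common, "gain": gain, "venn": venn}


# ---------------------------------------------------------------------------
# full chain on tracks


def chirp_true_peak_chain(
    even: CoverageTrack,
    odd: CoverageTrack,
    input_track: CoverageTrack,
    call_params: PeakCallParams = PeakCallParams(),
    filt: TruePeakFilter = TruePeakFilter(),
    min_recip_overlap: float = 0.5,
    max_summit_dist: int = 500,
) -> dict:
    """call (even, odd) -> match -> score -> filter; returns every stage."""
    combined = combine_tracks(even, odd)
    even_peaks = call_candidate_peaks(even, input_track, call_params, lane="even")
    odd_peaks = call_candidate_peaks(odd, input_track, call_params, lane="odd")
    raw_peaks = match_raw_peaks(
        even_peaks, odd_peaks, combined, min_recip_overlap, max_summit_dist
    )
    scored = [
        (rp, score_concordance(rp, even, odd, combined, input_track, filt))
        for rp in raw_peaks
    ]
    true_peaks = filter_true_peaks(scored, filt)
    quantify_peak_rpkm(combined, true_peaks)
    return {
        "even_peaks": even_peaks,
        "odd_peaks": odd_peaks,
        "raw_peaks": raw_peaks,
        "scored": scored,
        "true_peaks": true_peaks,
        "combined": combined,
    }
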