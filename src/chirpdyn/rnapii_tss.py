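"""RNAPII phosphoform TSS analytics.

Ser5-phosphorylated RNAPII marks initiating/promoter-proximal polymerase,
Ser2P marks elongating polymerase. This module builds metagene profile
matrices around TSSs, compares treated vs control densities (log2 fold
change), aligns heatmap rows to a reference peak position, computes
promoter escape indexes (gene-body over promoter-proximal mean coverage),
and estimates how far a released transcription wave has advanced along a
gene body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import CoverageTrack, GeneModel
from .rank_stats import benjamini_hochberg, mannwhitney_u

log = logging.getLogger(__name__)


@dataclass
class TSSProfileMatrix:
    """Genes x bins rpm signal over [TSS - flank, TSS + flank).

    Rows of minus-strand genes are reversed so bin 0 is always the most
    upstream position (5' -> 3' reading order).
    """

    gene_ids: list[str]
    matrix: np.ndarray  # shape (n_genes, n_bins)
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        n_bins = 2 * self.flank // self.bin_size
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n_bins:
            raise ValueError(f"expected {n_bins} bins, got {self.matrix.shape}")
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids / matrix row mismatch")
        if np.any(self.matrix < 0):
            raise ValueError("negative profile values")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Genomic offset of each bin's left edge relative to the TSS."""
        return np.arange(-self.flank, self.flank, self.bin_size)


@dataclass(frozen=True)
class ProfileComparison:
    """Per-bin log2 ratio of treated vs control mean density."""

    log2fc: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log2fc)):
            raise ValueError("non-finite log2 fold changes")


@dataclass(frozen=True)
class EscapeIndexParams:
    """Gene-body window [TSS+101, TSS+2000] (clipped at the TTS for short
    genes) over promoter-proximal window [TSS-100, TSS+100]."""

    body_start_offset: int = 101
    body_end_offset: int = 2000
    promoter_halfwidth: int = 100
    min_promoter_rpm: float = 0.1

    def __post_init__(self) -> None:
        if self.body_start_offset <= 0:
            raise ValueError("body_start_offset must be > 0")
        if self.promoter_halfwidth < 0:
            raise ValueError("promoter window must be non-empty")


def build_tss_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    flank: int = 2000,
    bin_size: int = 50,
) -> TSSProfileMatrix:
    """Mean rpm per bin around each gene's TSS, strand-oriented.

    Genes whose TSS is closer than ``flank`` to a chromosome edge are
    dropped (count logged).
    """
    if track.norm != "rpm":
        raise ValueError("profile matrices are built from rpm tracks")
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide 2*flank")
    n_bins = 2 * flank // bin_size
    rows, ids = [], []
    dropped = 0
    for g in genes:
        clen = track.chrom_sizes[g.chrom]
        # anchor on the TSS boundary (start for +, end for -) so reflecting
        # the genome and flipping strands leaves rows exactly unchanged
        boundary = g.interval.start if g.strand == "+" else g.interval.end
        lo, hi = boundary - flank, boundary + flank
        if lo < 0 or hi > clen:
            dropped += 1
            continue
        vals = track.values(g.chrom, lo, hi)
        row = vals.reshape(n_bins, bin_size).mean(axis=1)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    if dropped:
        log.info("build_tss_matrix: dropped %d genes near chromosome edges", dropped)
    matrix = np.array(rows) if rows else np.empty((0, n_bins))
    return TSSProfileMatrix(ids, matrix, flank, bin_size)


def average_profile(matrix: TSSProfileMatrix) -> np.ndarray:
    """Per-bin mean over genes (a metagene average plot)."""
    if matrix.matrix.shape[0] == 0:
        raise ValueError("empty profile matrix")
    return matrix.matrix.mean(axis=0)


def log2fc_profile(
    treated: TSSProfileMatrix,
    control: TSSProfileMatrix,
    epsilon: float = 0.25,
) -> ProfileComparison:
    """log2((mean_treated + eps) / (mean_control + eps)) per bin."""
    if treated.gene_ids != control.gene_ids:
        raise ValueError("treated and control matrices cover different genes")
    if treated.n_bins != control.n_bins:
        raise ValueError("bin layout mismatch")
    mt = average_profile(treated)
    mc = average_profile(control)
    return ProfileComparison(np.log2((mt + epsilon) / (mc + epsilon)), epsilon)


def heatmap_rows(
    matrix_ref: TSSProfileMatrix, matrices: list[TSSProfileMatrix]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Re-center every row on the reference matrix's per-gene peak bin.

    Each gene's window is shifted so the bin of maximal reference signal
    (leftmost argmax on ties) sits at the center bin; the same shift is
    applied to every matrix, padding with zeros. Rows come back ordered by
    descending reference row mean (stable sort).
    """
    for m in matrices:
        if m.gene_ids != matrix_ref.gene_ids or m.n_bins != matrix_ref.n_bins:
            raise ValueError("matrices must share genes and bin layout")
    n_genes, n_bins = matrix_ref.matrix.shape
    center = n_bins // 2
    shifts = np.argmax(matrix_ref.matrix, axis=1) - center  # leftmost argmax

    def shifted(mat: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mat)
        for i in range(n_genes):
            s = shifts[i]
            src_lo, src_hi = max(0, s), min(n_bins, n_bins + s)
            dst_lo, dst_hi = max(0, -s), min(n_bins, n_bins - s)
            out[i, dst_lo:dst_hi] = mat[i, src_lo:src_hi]
        return out

    order = np.argsort(-matrix_ref.matrix.mean(axis=1), kind="stable")
    aligned = [shifted(m.matrix)[order] for m in matrices]
    return order, aligned


# ---------------------------------------------------------------------------
# promoter escape index


def escape_index(
    track: CoverageTrack,
    gene: GeneModel,
    params: EscapeIndexParams = EscapeIndexParams(),
) -> float:
    """Mean gene-body rpm over mean promoter-proximal rpm (NaN when the
    promoter signal is below ``min_promoter_rpm`` or the body is empty).

    The body runs from 101 bases downstream of the TSS to 2 kb downstream,
    or to the TTS for genes shorter than 2 kb; the promoter-proximal window
    is TSS +/- 100 (both strand-aware).
    """
    if track.norm != "rpm":
        raise ValueError("escape index is defined on rpm tracks")
    tss, tts = gene.tss, gene.tts
    clen = track.chrom_sizes[gene.chrom]
    hw = params.promoter_halfwidth
    if gene.strand == "+":
        prom_lo, prom_hi = tss - hw, tss + hw + 1
        body_lo = tss + params.body_start_offset
        body_hi = min(tss + params.body_end_offset, tts) + 1
    else:
        prom_lo, prom_hi = tss - hw, tss + hw + 1
        body_hi = tss - params.body_start_offset + 1
        body_lo = max(tss - params.body_end_offset, tts)
    if (gene.strand == "+" and tts <= tss + params.body_start_offset) or (
        gene.strand == "-" and tts >= tss - params.body_start_offset
    ):
        log.warning("escape_index: gene %s body is empty", gene.gene_id)
        return float("nan")
    prom_lo, prom_hi = max(0, prom_lo), min(clen, prom_hi)
    body_lo, body_hi = max(0, body_lo), min(clen, body_hi)
    prom_mean = track.mean(gene.chrom, prom_lo, prom_hi)
    if prom_mean < params.min_promoter_rpm:
        return float("nan")
    body_mean = track.mean(gene.chrom, body_lo, body_hi)
    return body_mean / prom_mean


def escape_index_table(
    track: CoverageTrack,
    genes: list[GeneModel],
    params: EscapeIndexParams = EscapeIndexParams(),
) -> dict[str, float]:
    """Per-gene escape index (NaN entries kept so callers can count them)."""
    return {g.gene_id: escape_index(track, g, params) for g in genes}


def ei_ecdf(ei_values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF over the defined (non-NaN) escape indexes.

    Returns (x, F) where x are the sorted unique values and F(x_i) the
    fraction of values <= x_i; F of the maximum is 1.
    """
    vals = np.asarray(list(ei_values), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined escape indexes")
    x = np.unique(vals)
    counts = np.searchsorted(np.sort(vals), x, side="right")
    return x, counts / vals.size


def mannwhitney_bh(
    groups: list[tuple[str, np.ndarray]],
    comparisons: list[tuple[str, str]],
) -> list[dict]:
    """Two-sided Mann-Whitney per comparison with BH adjustment across the
    family. Returns one record per comparison with U, p_raw and p_adj."""
    if not comparisons:
        raise ValueError("empty comparison family")
    samples = dict(groups)
    results = []
    for a, b in comparisons:
        u, p = mannwhitney_u(samples[a], samples[b])
        results.append({"group_a": a, "group_b": b, "U": u, "p_raw": p})
    p_adj = benjamini_hochberg([r["p_raw"] for r in results])
    for r, pa in zip(results, p_adj):
        r["p_adj"] = float(pa)
    return results


# ---------------------------------------------------------------------------
# transcription wave-front detection


def detect_wavefront(
    track: CoverageTrack,
    gene: GeneModel,
    background_rpm: float,
    smooth_bases: int = 1000,
    factor: float = 3.0,
    max_gap: int = 2000,
) -> float:
    """Farthest gene-body position (bases downstream of the TSS) reached by
    a contiguous wave of above-background signal.

    The per-base rpm along the gene (TSS -> TTS orientation) is smoothed
    with a centered moving average over ``smooth_bases``; the wave-front is
    the farthest downstream position at or above ``factor * background_rpm``
    that is not separated from the TSS by a sub-threshold run longer than
    ``max_gap``. Returns NaN when the promoter itself is sub-threshold.
    """
    if background_rpm <= 0:
        raise ValueError("background_rpm must be > 0")
    if track.norm != "rpm":
        raise ValueError("wave-front detection expects an rpm track")
    if gene.length <= smooth_bases:
        raise ValueError("gene shorter than the smoothing window")
    vals = track.values(gene.chrom, gene.interval.start, gene.interval.end)
    if gene.strand == "-":
        vals = vals[::-1]  # index 0 = TSS for both strands
    kernel = np.ones(smooth_bases) / smooth_bases
    smoothed = np.convolve(vals, kernel, mode="same")
    above = smoothed >= factor * background_rpm
    if not above[0]:
        return float("nan")
    gap = 0
    front = 0
    for i in range(1, len(above)):
        if above[i]:
            gap = 0
            front = i
        else:
            gap += 1
            if gap > max_gap:
                break
    return float(front)
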