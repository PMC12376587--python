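"""Synthetic data with planted ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed), using NumPy's
PCG64 generator for portable, bitwise-reproducible streams. Read counts
are modeled as Poisson draws at the base level (not read placement), which
is adequate for the coverage statistics the pipeline computes and fast at
desk scale. Truth objects carry everything needed to score
recall/precision/ARI without re-reading generator internals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
)


@dataclass
class SimTruth:
    """Machine-readable record of what a generator planted."""

    kind: str
    seed: int
    params: dict
    records: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], d["seed"], d["params"], d["records"])


# ---------------------------------------------------------------------------
# genome


def make_genome(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    n_genes: int = 100,
    min_gene_len: int = 3000,
    max_gene_len: int = 8000,
    seed: int = 0,
    edge_margin: int = 10_000,
    min_gap: int = 1000,
    lnc_fraction: float = 0.0,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping genes with random strands and 2-8 exons.

    Genes are distributed evenly across chromosomes and spaced by random
    gaps of at least ``min_gap``; an infeasible packing raises before any
    output is produced.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    gid = 0
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        n_c = per_chrom[ci]
        if n_c == 0:
            continue
        lengths = rng.integers(min_gene_len, max_gene_len + 1, size=n_c)
        usable = chrom_len - 2 * edge_margin
        slack = usable - int(lengths.sum()) - n_c * min_gap
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_c} genes of total length {lengths.sum()} "
                f"into {usable} usable bases on {chrom}"
            )
        extra = rng.multinomial(slack, np.full(n_c, 1.0 / n_c))
        pos = edge_margin
        for i in range(n_c):
            pos += min_gap + int(extra[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_id = f"gene{gid:04d}"
            biotype = "lncRNA" if rng.random() < lnc_fraction else "coding"
            exons = _make_exons(chrom, start, end, strand, rng)
            genes.append(
                GeneModel(
                    gene_id,
                    GenomicInterval(chrom, start, end, strand, gene_id),
                    exons,
                    biotype,
                )
            )
    return genes, chrom_sizes


def _make_exons(chrom, start, end, strand, rng) -> tuple[GenomicInterval, ...]:
    n_ex = int(rng.integers(2, 9))
    length = end - start
    n_cuts = 2 * n_ex - 2
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = np.concatenate(([0], cuts, [length]))
    exons = []
    for k in range(0, len(bounds) - 1, 2):  # segments 0, 2, 4, ... are exons
        exons.append(
            GenomicInterval(chrom, start + int(bounds[k]), start + int(bounds[k + 1]), strand)
        )
    return tuple(exons)


# ---------------------------------------------------------------------------
# ChIRP even/odd/input triple


def simulate_chirp(
    chrom_sizes: dict[str, int],
    n_concordant: int = 200,
    n_even_only: int = 100,
    n_odd_only: int = 100,
    background: float = 1.0,
    enrichment: float = 5.0,
    peak_len: int = 500,
    library_size: float | None = None,
    seed: int = 0,
    edge_margin: int = 10_000,
) -> tuple[dict[str, CoverageTrack], SimTruth]:
    """Even/odd/input track triple with planted concordant peaks and
    lane-specific decoys over Poisson background.

    Planted sites add a Gaussian-shaped bump (sigma = peak_len/4) scaled so
    the mean signal over the planted interval equals
    ``enrichment x background``; concordant sites appear in both probe
    lanes, decoys in only one, so a shape-concordance filter separates
    them. The bump shape (rather than a flat rectangle) gives concordant
    sites the shared within-window structure that drives the even/odd
    Pearson statistic. The truth lists every planted interval with its
    lane provenance.

    ``library_size`` is the nominal sequencing depth recorded on every
    lane; it defaults to the expected background mass
    (background x genome length), i.e. depth-matched lanes, so rpm units
    mean the same thing in all three tracks regardless of how much planted
    signal a lane carries.
    """
    rng = np.random.default_rng(seed)
    n_total = n_concordant + n_even_only + n_odd_only
    kinds = np.array(
        ["concordant"] * n_concordant
        + ["even_only"] * n_even_only
        + ["odd_only"] * n_odd_only
    )
    kinds = kinds[rng.permutation(n_total)]

    chroms = sorted(chrom_sizes)
    total_len = sum(chrom_sizes.values())
    # proportional slot allocation, evenly spaced centers with jitter
    placements: list[tuple[str, int]] = []
    assigned = 0
    for i, chrom in enumerate(chroms):
        if i == len(chroms) - 1:
            n_c = n_total - assigned
        else:
            n_c = int(round(n_total * chrom_sizes[chrom] / total_len))
        assigned += n_c
        usable = chrom_sizes[chrom] - 2 * edge_margin
        if n_c == 0:
            continue
        slot = usable / n_c
        if slot < peak_len * 4:
            raise ValueError("peaks cannot be placed without crowding")
        for j in range(n_c):
            jitter = rng.uniform(-0.2, 0.2) * slot
            center = int(edge_margin + (j + 0.5) * slot + jitter)
            placements.append((chrom, center))

    mean_conc = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    mean_even = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    mean_odd = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    records = []
    sigma = peak_len / 4.0
    for (chrom, center), kind in zip(placements, kinds):
        s, e = center - peak_len // 2, center + peak_len // 2
        x = np.arange(s, e)
        shape = np.exp(-0.5 * ((x - center) / sigma) ** 2)
        # interval mean = enrichment * background
        bump = background * (enrichment - 1.0) * shape / shape.mean()
        target = {"concordant": mean_conc, "even_only": mean_even,
                  "odd_only": mean_odd}[kind]
        target[chrom][s:e] += bump
        records.append(
            {"chrom": chrom, "start": int(s), "end": int(e),
             "center": int(center), "kind": kind}
        )

    tracks = {}
    data_in, data_ev, data_od = {}, {}, {}
    for chrom, n in chrom_sizes.items():
        data_in[chrom] = rng.poisson(background, n).astype(float)
        data_ev[chrom] = rng.poisson(
            background + mean_conc[chrom] + mean_even[chrom]
        ).astype(float)
        data_od[chrom] = rng.poisson(
            background + mean_conc[chrom] + mean_odd[chrom]
        ).astype(float)
    if library_size is None:
        library_size = background * sum(chrom_sizes.values())
    for name, data in (("input", data_in), ("even", data_ev), ("odd", data_od)):
        tracks[name] = CoverageTrack(data, dict(chrom_sizes), float(library_size))

    truth = SimTruth(
        "chirp",
        seed,
        {
            "n_concordant": n_concordant,
            "n_even_only": n_even_only,
            "n_odd_only": n_odd_only,
            "background": background,
            "enrichment": enrichment,
            "peak_len": peak_len,
        },
        records,
    )
    return tracks, truth


def evaluate_chirp_recovery(true_peaks, truth: SimTruth) -> dict[str, float]:
    """Recall on planted concordant sites and decoy retention rate.

    A planted site counts as recovered/retained when any true-peak interval
    overlaps it.
    """
    def hit(rec) -> bool:
        iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"])
        return any(tp.interval.overlap(iv) > 0 for tp in true_peaks)

    planted = [r for r in truth.records if r["kind"] == "concordant"]
    decoys = [r for r in truth.records if r["kind"] != "concordant"]
    recall = sum(hit(r) for r in planted) / max(1, len(planted))
    decoy_rate = sum(hit(r) for r in decoys) / max(1, len(decoys))
    return {
        "recall": recall,
        "decoy_retention": decoy_rate,
        "n_planted": len(planted),
        "n_decoys": len(decoys),
    }


# ---------------------------------------------------------------------------
# RNAPII Ser5P / Ser2P UV response


def simulate_rnapii(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    promoter_height: float = 20.0,
    body_level: float = 2.0,
    ser2p_body_level: float = 5.0,
    delta5: float = 0.5,
    delta2: float = 0.5,
    background: float = 0.2,
    seed: int = 0,
    promoter_halfwidth: int = 100,
    body_start_offset: int = 101,
) -> tuple[dict[str, CoverageTrack], SimTruth]:
    """Paired UV-/UV+ Ser5P and Ser2P tracks with planted promoter-peak
    depletion (delta5) and downstream gain (delta2).

    Ser5P piles on the promoter-proximal window (TSS +/- 100); UV scales
    that window by (1 - delta5). Ser2P weights the gene body (TSS+101 to
    TTS); UV scales the body by (1 + delta2). Poisson noise is overlaid.
    All four tracks share one nominal library size (depth-matched
    sequencing by construction) so planted effect sizes appear directly in
    rpm space; the analytically planted escape-index ratio
    (background + promoter) / (background + (1-delta5) * promoter) is
    recorded in the truth.
    """
    if not (0.0 <= delta5 <= 1.0):
        raise ValueError("delta5 must lie in [0, 1]")
    if delta2 < 0:
        raise ValueError("delta2 must be >= 0")
    for v in (promoter_height, body_level, ser2p_body_level, background):
        if v <= 0:
            raise ValueError("signal levels must be positive")
    rng = np.random.default_rng(seed)

    def blank():
        return {c: np.full(n, background, dtype=float) for c, n in chrom_sizes.items()}

    means = {
        "ser5p_control": blank(),
        "ser5p_uv": blank(),
        "ser2p_control": blank(),
        "ser2p_uv": blank(),
    }
    hw = promoter_halfwidth
    for g in genes:
        tss = g.tss
        clen = chrom_sizes[g.chrom]
        p_lo, p_hi = max(0, tss - hw), min(clen, tss + hw + 1)
        if g.strand == "+":
            b_lo, b_hi = tss + body_start_offset, g.tts + 1
        else:
            b_lo, b_hi = g.tts, tss - body_start_offset + 1
        b_lo, b_hi = max(0, b_lo), min(clen, b_hi)
        means["ser5p_control"][g.chrom][p_lo:p_hi] += promoter_height
        means["ser5p_uv"][g.chrom][p_lo:p_hi] += promoter_height * (1 - delta5)
        if b_hi > b_lo:
            for key in ("ser5p_control", "ser5p_uv"):
                means[key][g.chrom][b_lo:b_hi] += body_level
            means["ser2p_control"][g.chrom][b_lo:b_hi] += ser2p_body_level
            means["ser2p_uv"][g.chrom][b_lo:b_hi] += ser2p_body_level * (1 + delta2)

    nominal_lib = float(sum(a.sum() for a in means["ser5p_control"].values()))
    tracks = {}
    for name in sorted(means):
        data = {c: rng.poisson(m).astype(float) for c, m in sorted(means[name].items())}
        tracks[name] = CoverageTrack(data, dict(chrom_sizes), nominal_lib)

    planted_ei_ratio = (background + body_level) / (background + body_level) * (
        (background + promoter_height)
        / (background + promoter_height * (1 - delta5))
    )
    truth = SimTruth(
        "rnapii",
        seed,
        {
            "promoter_height": promoter_height,
            "body_level": body_level,
            "ser2p_body_level": ser2p_body_level,
            "delta5": delta5,
            "delta2": delta2,
            "background": background,
            "planted_ei_ratio": planted_ei_ratio,
            "nominal_library_size": nominal_lib,
        },
        [],
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# expression time course


def simulate_expression(
    n_per_cluster: int = 300,
    timepoints=(0.0, 3.0, 6.0, 12.0, 24.0, 48.0),
    centroid_shapes: np.ndarray | None = None,
    amplitude: float = 2.0,
    noise_sd: float = 0.5,
    fpkm_scale: float = 10.0,
    seed: int = 0,
    condition: str = "UV",
) -> tuple[ExpressionMatrix, np.ndarray, SimTruth]:
    """FPKM time courses with planted single-timepoint clusters.

    By default cluster i peaks (amplitude ``amplitude`` in log2 units) at
    timepoint i and is flat elsewhere. FPKM = fpkm_scale * 2^shape plus
    Gaussian noise of SD ``noise_sd * fpkm_scale``, truncated at 0. Returns
    the matrix, the planted integer labels, and the truth record.
    """
    timepoints = [float(t) for t in timepoints]
    if centroid_shapes is None:
        k = len(timepoints)
        centroid_shapes = np.zeros((k, k))
        np.fill_diagonal(centroid_shapes, amplitude)
    centroid_shapes = np.asarray(centroid_shapes, dtype=float)
    if centroid_shapes.shape[1] != len(timepoints):
        raise ValueError("centroid shapes must have one column per timepoint")
    if len(np.unique(centroid_shapes, axis=0)) != len(centroid_shapes):
        raise ValueError("duplicate centroid shapes")
    k = centroid_shapes.shape[0]
    rng = np.random.default_rng(seed)

    labels = np.repeat(np.arange(k), n_per_cluster)
    base = fpkm_scale * np.power(2.0, centroid_shapes[labels])
    noise = rng.normal(0.0, noise_sd * fpkm_scale, size=base.shape)
    fpkm = np.clip(base + noise, 0.0, None)

    ids = [f"tx{i + 1:05d}" for i in range(len(labels))]
    cols = pd.MultiIndex.from_tuples(
        [(condition, t) for t in timepoints], names=["condition", "time"]
    )
    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=ids, columns=cols))
    truth = SimTruth(
        "expression",
        seed,
        {
            "n_per_cluster": n_per_cluster,
            "timepoints": timepoints,
            "amplitude": amplitude,
            "noise_sd": noise_sd,
            "fpkm_scale": fpkm_scale,
            "k": int(k),
        },
        [{"transcript_id": t, "cluster": int(c)} for t, c in zip(ids, labels)],
    )
    return matrix, labels, truth
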