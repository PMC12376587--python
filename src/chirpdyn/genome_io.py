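"""Core genomic data model and plain-text format I/O.

All coordinates are 0-based half-open internally (BED convention). GTF input
(1-based, closed) is converted on read and back on write. Coverage is held as
dense per-chromosome vectors at a configurable bin size (default 1 base),
which keeps arithmetic exact at the scale this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in an input file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bases between two intervals; 0 if they overlap or abut,
        None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS/TTS and exon structure.

    TSS is interval.start on the + strand and interval.end - 1 on the -
    strand (the last covered base under the half-open convention); TTS is
    the opposite terminus.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside "
                    f"gene bounds {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Peak:
    """Called peak with summit position, -log10 p score and fold enrichment."""

    interval: GenomicInterval
    summit: int
    score: float
    fold_enrichment: float
    lane: str = "combined"

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


@dataclass
class CoverageTrack:
    """Dense per-chromosome signal at ``bin_size`` resolution.

    ``data[chrom][i]`` is the mean signal over bases
    [i*bin_size, (i+1)*bin_size). ``norm`` is "raw" (read counts) or "rpm".
    """

    data: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    library_size: float
    bin_size: int = 1
    norm: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.norm not in ("raw", "rpm"):
            raise ValueError(f"unknown norm {self.norm!r}")
        for chrom, arr in self.data.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} missing from chrom_sizes")
            n_bins = _n_bins(self.chrom_sizes[chrom], self.bin_size)
            if len(arr) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(arr)}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative coverage values")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end) (bins expanded if bin_size > 1)."""
        if end > self.chrom_sizes[chrom] or start < 0 or start >= end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome bounds"
            )
        arr = self.data[chrom]
        if self.bin_size == 1:
            return arr[start:end]
        per_base = np.repeat(arr, self.bin_size)[: self.chrom_sizes[chrom]]
        return per_base[start:end]

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(np.mean(self.values(chrom, start, end)))

    def total_signal(self) -> float:
        return float(sum(arr.sum() * self.bin_size for arr in self.data.values()))

    def genome_length(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.data)


def _n_bins(chrom_len: int, bin_size: int) -> int:
    return math.ceil(chrom_len / bin_size)


def zero_track(
    chrom_sizes: dict[str, int], library_size: float = 0.0, bin_size: int = 1
) -> CoverageTrack:
    data = {
        c: np.zeros(_n_bins(n, bin_size), dtype=float)
        for c, n in chrom_sizes.items()
    }
    return CoverageTrack(data, dict(chrom_sizes), library_size, bin_size)


def to_rpm(track: CoverageTrack) -> CoverageTrack:
    """Reads-per-million normalization: values * 1e6 / library_size."""
    if track.norm != "raw":
        raise ValueError("track is already rpm-normalized")
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0 for rpm normalization")
    factor = 1e6 / track.library_size
    data = {c: arr * factor for c, arr in track.data.items()}
    return CoverageTrack(
        data, dict(track.chrom_sizes), track.library_size, track.bin_size, "rpm"
    )


def combine_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Base-wise sum of two raw tracks with summed library sizes."""
    if a.norm != "raw" or b.norm != "raw":
        raise ValueError("can only combine raw tracks")
    if set(a.data) != set(b.data) or a.bin_size != b.bin_size:
        raise ValueError("tracks must share chromosomes and bin size")
    data = {c: a.data[c] + b.data[c] for c in a.data}
    return CoverageTrack(
        data, dict(a.chrom_sizes), a.library_size + b.library_size, a.bin_size
    )


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path,
    chrom_sizes: dict[str, int],
    library_size: float | None = None,
    bin_size: int = 1,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a raw CoverageTrack.

    Untouched positions are zero. Overlapping records are an error, as are
    records extending past the stated chromosome length. If ``library_size``
    is None it defaults to the total signal in the file.
    """
    records: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative coverage value {value}")
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{ln}: invalid interval {start}-{end}")
            if end > chrom_sizes[chrom]:
                raise ValueError(
                    f"{path}:{ln}: record ends at {end}, beyond {chrom} "
                    f"length {chrom_sizes[chrom]}"
                )
            records[chrom].append((start, end, value))

    track = zero_track(chrom_sizes, 0.0, bin_size)
    total = 0.0
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        arr = track.data[chrom]
        for start, end, value in recs:
            if start < prev_end:
                raise ValueError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            prev_end = end
            total += value * (end - start)
            if bin_size == 1:
                arr[start:end] += value
            else:
                # distribute value into bins proportionally to base overlap
                b0, b1 = start // bin_size, (end - 1) // bin_size
                for b in range(b0, b1 + 1):
                    lo = max(start, b * bin_size)
                    hi = min(end, (b + 1) * bin_size)
                    arr[b] += value * (hi - lo) / bin_size
    track.library_size = float(library_size) if library_size is not None else total
    return track


def write_bedgraph(track: CoverageTrack, path, precision: int = 6) -> None:
    """Write non-zero runs of a track as bedGraph (run-length compressed)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.data[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            bs = track.bin_size
            clen = track.chrom_sizes[chrom]
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{s * bs}\t{min(e * bs, clen)}\t{v:.{precision}g}\n"
                )


# ---------------------------------------------------------------------------
# gene annotations


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_genes(path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from a minimal GTF (gene/exon features) or TSV.

    The TSV dialect has a header line and columns: gene_id, chrom, start,
    end, strand, biotype, exon_starts, exon_ends (comma-separated, 0-based
    half-open, matching the internal convention).
    """
    if format == "gtf":
        return _read_genes_gtf(path)
    if format == "tsv":
        return _read_genes_tsv(path)
    raise ValueError(f"unknown gene format {format!r}")


def _read_genes_gtf(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: unknown strand {strand!r}")
            start, end = int(start1) - 1, int(end1)  # GTF is 1-based closed
            attrs = _parse_gtf_attrs(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{ln}: missing gene_id attribute")
            rec = genes.setdefault(
                gid, {"interval": None, "exons": [], "biotype": "other"}
            )
            if gid not in order:
                order.append(gid)
            if feature == "gene":
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", "other"))
                rec["interval"] = GenomicInterval(chrom, start, end, strand, gid)
                rec["biotype"] = _canonical_biotype(biotype)
            else:
                rec["exons"].append(GenomicInterval(chrom, start, end, strand))

    out = []
    for gid in order:
        rec = genes[gid]
        if rec["interval"] is None:
            raise ValueError(f"{path}: exon without gene feature for {gid!r}")
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        out.append(GeneModel(gid, rec["interval"], exons, rec["biotype"]))
    return out


def _canonical_biotype(raw: str) -> str:
    if raw in ("coding", "protein_coding"):
        return "coding"
    if raw in ("lncRNA", "lincRNA"):
        return "lncRNA"
    return "other"


def _read_genes_tsv(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required <= set(idx):
            raise ParseError(f"{path}: missing required columns {required - set(idx)}")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            interval = GenomicInterval(
                f[idx["chrom"]],
                int(f[idx["start"]]),
                int(f[idx["end"]]),
                f[idx["strand"]],
                f[idx["gene_id"]],
            )
            exons: tuple[GenomicInterval, ...] = ()
            if "exon_starts" in idx and f[idx["exon_starts"]]:
                starts = [int(x) for x in f[idx["exon_starts"]].split(",") if x]
                ends = [int(x) for x in f[idx["exon_ends"]].split(",") if x]
                exons = tuple(
                    GenomicInterval(interval.chrom, s, e, interval.strand)
                    for s, e in zip(starts, ends)
                )
            biotype = f[idx["biotype"]] if "biotype" in idx else "coding"
            out.append(GeneModel(f[idx["gene_id"]], interval, exons, biotype))
    return out


def write_genes_gtf(genes: list[GeneModel], path, source: str = "chirpdyn") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# peak files


def write_peaks(peaks, path, format: str = "narrowPeak") -> None:
    """Write peaks as BED6 or narrowPeak (BED6+4).

    narrowPeak column 10 is the summit offset relative to the interval start;
    integer fields round-trip bit-exactly through :func:`read_peaks`.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.interval.name or f"peak_{i + 1}"
            base = (
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{name}\t{int(round(min(1000.0, p.score)))}\t{p.interval.strand}"
            )
            if format == "bed6":
                fh.write(base + "\n")
            else:
                fh.write(
                    base
                    + f"\t{p.fold_enrichment:.6g}\t{p.score:.6g}\t-1"
                    + f"\t{p.summit - p.interval.start}\n"
                )


def read_peaks(path, format: str = "narrowPeak", lane: str = "combined") -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            n_expected = 6 if format == "bed6" else 10
            if len(f) < n_expected:
                raise ParseError(
                    f"{path}:{ln}: expected {n_expected} columns, got {len(f)}"
                )
            interval = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5], f[3])
            if format == "bed6":
                peaks.append(
                    Peak(interval, interval.start, float(f[4]), 0.0, lane)
                )
            else:
                peaks.append(
                    Peak(
                        interval,
                        interval.start + int(f[9]),
                        float(f[7]),
                        float(f[6]),
                        lane,
                    )
                )
    return peaks


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Transcript x sample FPKM matrix.

    Column labels are (condition, timepoint-hours) pairs parsed from the
    "condition:time" TSV header convention.
    """

    values: "object"  # pandas.DataFrame, index transcript_id

    def __post_init__(self) -> None:
        import pandas as pd

        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a DataFrame")
        if df.isna().any().any():
            raise ValueError("expression matrix has missing cells")
        if (df.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if df.columns.duplicated().any():
            raise ValueError("duplicate (condition, timepoint) columns")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.values.columns})

    def timepoints(self, condition: str) -> list[float]:
        return sorted(t for c, t in self.values.columns if c == condition)

    def condition_frame(self, condition: str):
        """Sub-frame for one condition with columns ordered by timepoint."""
        cols = [(c, t) for c, t in self.values.columns if c == condition]
        cols.sort(key=lambda ct: ct[1])
        return self.values[cols]


def read_expression(path) -> ExpressionMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for col in df.columns:
        cond, _, t = str(col).partition(":")
        if not t:
            raise ParseError(f"{path}: column {col!r} not in 'condition:time' form")
        cols.append((cond, float(t)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "time"])
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{c}:{t:g}" for c, t in df.columns]
    df.to_csv(path, sep="\t", index_label="transcript_id")
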