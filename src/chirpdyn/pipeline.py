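"""End-to-end workflows chaining the analysis stages.

Each ``run_*`` function consumes a resolved configuration dictionary
(defaults < config file < explicit overrides), writes machine-readable
outputs (JSON report, TSV tables) plus a manifest of input checksums and
parameters, and returns the report. Tracks and annotations may be passed
in memory to skip file loading (the CLI always goes through files).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import chirp_truepeaks as ctp
from . import genome_io as gio
from . import rnapii_tss as rtss
from . import temporal_expression as texp

log = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "out": "chirpdyn_out",
    "log_level": "INFO",
    "chirp": {
        "even": "",
        "odd": "",
        "input": "",
        "chrom_sizes": "",
        "genes": "",
        "genes_format": "gtf",
        "p_cutoff": 1e-5,
        "window": 300,
        "step": 50,
        "local_lambda_span": 10_000,
        "min_gap": 100,
        "min_len": 150,
        "pseudocount": 0.5,
        "min_recip_overlap": 0.5,
        "max_summit_dist": 500,
        "min_avg_coverage": 1.5,
        "min_fold_enrichment": 2.0,
        "min_pearson": 0.3,
        "window_halfwidth": 2000,
        "upstream_ext": 2000,
    },
    "tss": {
        "ser5p_control": "",
        "ser5p_uv": "",
        "ser2p_control": "",
        "ser2p_uv": "",
        "chrom_sizes": "",
        "genes": "",
        "genes_format": "gtf",
        "flank": 2000,
        "bin_size": 50,
        "epsilon": 0.25,
        "min_promoter_rpm": 0.1,
    },
    "temporal": {
        "expression": "",
        "condition": "",
        "k": 6,
        "fuzzifier": 1.5,
        "tol": 1e-6,
        "max_iter": 500,
        "n_restarts": 5,
        "logfc_threshold": 0.75,
        "pseudo_fpkm": 0.1,
        "min_margin": 0.5,
        "min_shift": False,
    },
}


def resolve_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults < TOML config file < overrides; unknown keys are
    rejected so typos fail loudly."""
    cfg = copy.deepcopy(DEFAULTS)
    layers = []
    if path is not None:
        with open(path, "rb") as fh:
            layers.append(tomllib.load(fh))
    if overrides:
        layers.append(overrides)
    for layer in layers:
        _merge(cfg, layer, [])
    return cfg


def _merge(base: dict, update: dict, trail: list[str]) -> None:
    for key, value in update.items():
        if key not in base:
            where = ".".join(trail + [str(key)])
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"section {key!r} must be a table")
            _merge(base[key], value, trail + [str(key)])
        else:
            base[key] = value


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, cfg: dict, input_paths: dict[str, str]) -> None:
    manifest = {
        "tool_version": __version__,
        "parameters": cfg,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in input_paths.items()
            if p and Path(p).exists()
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    with open(out_dir / "run_config.resolved", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)


def _load_track(path, chrom_sizes) -> gio.CoverageTrack:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input track: {p}")
    return gio.read_bedgraph(p, chrom_sizes)


# ---------------------------------------------------------------------------
# ChIRP pipeline


def run_chirp_pipeline(cfg: dict, tracks=None, genes=None) -> dict:
    """call -> match -> score -> filter -> annotate -> target genes."""
    c = cfg["chirp"]
    out_dir = Path(cfg["out"])
    inputs = {}
    if tracks is None:
        chrom_sizes = gio.read_chrom_sizes(c["chrom_sizes"])
        tracks = {
            name: _load_track(c[name], chrom_sizes)
            for name in ("even", "odd", "input")
        }
        inputs = {k: c[k] for k in ("even", "odd", "input", "chrom_sizes")}
    if genes is None and c["genes"]:
        genes = gio.read_genes(c["genes"], c["genes_format"])
        inputs["genes"] = c["genes"]

    call_params = ctp.PeakCallParams(
        p_cutoff=c["p_cutoff"],
        window=c["window"],
        step=c["step"],
        local_lambda_span=c["local_lambda_span"],
        min_gap=c["min_gap"],
        min_len=c["min_len"],
        pseudocount=c["pseudocount"],
    )
    filt = ctp.TruePeakFilter(
        min_avg_coverage=c["min_avg_coverage"],
        min_fold_enrichment=c["min_fold_enrichment"],
        min_pearson=c["min_pearson"],
        window_halfwidth=c["window_halfwidth"],
    )
    result = ctp.chirp_true_peak_chain(
        tracks["even"],
        tracks["odd"],
        tracks["input"],
        call_params,
        filt,
        c["min_recip_overlap"],
        c["max_summit_dist"],
    )

    report = {
        "n_even_candidates": len(result["even_peaks"]),
        "n_odd_candidates": len(result["odd_peaks"]),
        "n_raw_peaks": len(result["raw_peaks"]),
        "n_true_peaks": len(result["true_peaks"]),
    }
    if genes:
        annos, hist = ctp.annotate_peaks(result["true_peaks"], genes)
        targets = ctp.assign_target_genes(
            result["true_peaks"], genes, c["upstream_ext"]
        )
        report["annotation_fractions"] = hist
        report["n_target_genes"] = len(targets)
        result["annotations"] = annos
        result["target_genes"] = targets

    out_dir.mkdir(parents=True, exist_ok=True)
    gio.write_peaks(
        [
            gio.Peak(
                tp.interval,
                tp.summit,
                tp.raw.even_peak.score,
                tp.score.fold_enrichment,
            )
            for tp in result["true_peaks"]
        ],
        out_dir / "true_peaks.narrowPeak",
    )
    scores = pd.DataFrame(
        [
            {
                "chrom": rp.interval.chrom,
                "start": rp.interval.start,
                "end": rp.interval.end,
                "summit": rp.summit,
                "avg_coverage": sc.avg_coverage,
                "fold_enrichment": sc.fold_enrichment,
                "pearson_r": sc.pearson_r,
            }
            for rp, sc in result["scored"]
        ]
    )
    scores.to_csv(out_dir / "concordance_scores.tsv", sep="\t", index=False)
    if genes and "target_genes" in result:
        (out_dir / "target_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(result["target_genes"]))
        )
    with open(out_dir / "chirp_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    write_manifest(out_dir, cfg, inputs)
    result["report"] = report
    return result


# ---------------------------------------------------------------------------
# TSS pipeline


TRACK_KEYS = ("ser5p_control", "ser5p_uv", "ser2p_control", "ser2p_uv")


def run_tss_pipeline(cfg: dict, tracks=None, genes=None) -> dict:
    """Profile matrices, average and log2FC profiles, escape indexes and
    rank statistics for the four condition/antibody tracks."""
    t = cfg["tss"]
    out_dir = Path(cfg["out"])
    inputs = {}
    if tracks is None:
        chrom_sizes = gio.read_chrom_sizes(t["chrom_sizes"])
        tracks = {k: _load_track(t[k], chrom_sizes) for k in TRACK_KEYS}
        inputs = {k: t[k] for k in TRACK_KEYS}
        inputs["chrom_sizes"] = t["chrom_sizes"]
    if genes is None:
        genes = gio.read_genes(t["genes"], t["genes_format"])
        inputs["genes"] = t["genes"]

    rpm = {k: gio.to_rpm(v) if v.norm == "raw" else v for k, v in tracks.items()}
    matrices = {
        k: rtss.build_tss_matrix(rpm[k], genes, t["flank"], t["bin_size"])
        for k in TRACK_KEYS
    }
    averages = {k: rtss.average_profile(m) for k, m in matrices.items()}
    log2fc = {
        "ser5p": rtss.log2fc_profile(
            matrices["ser5p_uv"], matrices["ser5p_control"], t["epsilon"]
        ),
        "ser2p": rtss.log2fc_profile(
            matrices["ser2p_uv"], matrices["ser2p_control"], t["epsilon"]
        ),
    }
    ei_params = rtss.EscapeIndexParams(min_promoter_rpm=t["min_promoter_rpm"])
    ei = {
        "control": rtss.escape_index_table(rpm["ser5p_control"], genes, ei_params),
        "uv": rtss.escape_index_table(rpm["ser5p_uv"], genes, ei_params),
    }

    # per-gene promoter-window mean density for the boxplot-style statistics
    n_prom = t["flank"] // t["bin_size"]
    prom_slice = slice(n_prom - 2, n_prom + 2)  # TSS +/- 2 bins
    groups = [
        (k, matrices[k].matrix[:, prom_slice].mean(axis=1)) for k in TRACK_KEYS
    ]
    ei_groups = [
        ("ei_control", np.array([v for v in ei["control"].values() if np.isfinite(v)])),
        ("ei_uv", np.array([v for v in ei["uv"].values() if np.isfinite(v)])),
    ]
    stats_records = rtss.mannwhitney_bh(
        groups + ei_groups,
        [
            ("ser5p_uv", "ser5p_control"),
            ("ser2p_uv", "ser2p_control"),
            ("ei_uv", "ei_control"),
        ],
    )

    ei_ctrl = ei_groups[0][1]
    ei_uv = ei_groups[1][1]
    report = {
        "n_genes_profiled": len(matrices["ser5p_control"].gene_ids),
        "median_ei_control": float(np.median(ei_ctrl)),
        "median_ei_uv": float(np.median(ei_uv)),
        "median_ei_ratio": float(np.median(ei_uv) / np.median(ei_ctrl)),
        "promoter_log2fc_ser5p": float(
            log2fc["ser5p"].log2fc[prom_slice].mean()
        ),
        "statistics": stats_records,
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    offsets = matrices["ser5p_control"].bin_offsets()
    prof = pd.DataFrame({"bin_start_offset": offsets})
    for k in TRACK_KEYS:
        prof[k] = averages[k]
    prof["log2fc_ser5p"] = log2fc["ser5p"].log2fc
    prof["log2fc_ser2p"] = log2fc["ser2p"].log2fc
    prof.to_csv(out_dir / "tss_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": list(ei["control"]),
            "ei_control": list(ei["control"].values()),
            "ei_uv": [ei["uv"][g] for g in ei["control"]],
        }
    ).to_csv(out_dir / "escape_index.tsv", sep="\t", index=False)
    pd.DataFrame(stats_records).to_csv(out_dir / "tss_stats.tsv", sep="\t", index=False)
    with open(out_dir / "tss_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    write_manifest(out_dir, cfg, inputs)
    return {
        "matrices": matrices,
        "averages": averages,
        "log2fc": log2fc,
        "escape_index": ei,
        "statistics": stats_records,
        "report": report,
    }


# ---------------------------------------------------------------------------
# temporal pipeline


def run_temporal_pipeline(
    cfg: dict,
    expr: gio.ExpressionMatrix | None = None,
    genes=None,
    term_map: dict[str, set[str]] | None = None,
) -> dict:
    """standardize -> select_dynamic -> soft_kmeans -> stage-specific
    clusters (-> targets, enrichment when annotations are supplied)."""
    tc = cfg["temporal"]
    out_dir = Path(cfg["out"])
    inputs = {}
    if expr is None:
        expr = gio.read_expression(tc["expression"])
        inputs["expression"] = tc["expression"]
    condition = tc["condition"] or expr.conditions()[0]
    frame = expr.condition_frame(condition)

    dynamic = texp.select_dynamic(
        frame,
        texp.DynamicSelectParams(tc["logfc_threshold"], tc["pseudo_fpkm"]),
    )
    standardized = texp.standardize(frame.loc[dynamic], min_shift=tc["min_shift"])
    result = texp.soft_kmeans(
        standardized,
        texp.ClusterParams(
            k=tc["k"],
            fuzzifier=tc["fuzzifier"],
            tol=tc["tol"],
            max_iter=tc["max_iter"],
            seed=cfg["seed"],
            n_restarts=tc["n_restarts"],
        ),
    )
    timepoints = [t for _, t in frame.columns]
    stage = texp.select_stage_specific(result, timepoints, tc["min_margin"])

    report = {
        "condition": condition,
        "n_transcripts": len(frame),
        "n_dynamic": len(dynamic),
        "n_clustered": len(standardized),
        "k": tc["k"],
        "n_stage_specific": len(stage),
        "stage_specific": stage,
    }

    out = {"dynamic": dynamic, "standardized": standardized,
           "clusters": result, "stage_specific": stage}
    if genes is not None:
        lnc = [g for g in genes if g.biotype == "lncRNA"]
        coding = [g for g in genes if g.biotype == "coding"]
        pairs = texp.predict_targets(lnc, coding, expr, condition=condition)
        out["targets"] = pairs
        report["n_target_pairs"] = len(pairs)
        if term_map is not None:
            universe = {g.gene_id for g in coding}
            targets = set(pairs["coding_gene"]) & universe
            enrich = texp.hypergeom_enrich(targets, universe, term_map)
            out["enrichment"] = enrich
            report["n_significant_terms"] = int(enrich["significant"].sum())

    out_dir.mkdir(parents=True, exist_ok=True)
    membership = pd.DataFrame(
        result.membership,
        index=result.transcript_ids,
        columns=[f"cluster_{i}" for i in range(tc["k"])],
    )
    membership["hard_label"] = result.labels
    membership.to_csv(out_dir / "cluster_membership.tsv", sep="\t",
                      index_label="transcript_id")
    pd.DataFrame(
        result.centroids,
        columns=[f"t{t:g}" for t in timepoints],
    ).to_csv(out_dir / "cluster_centroids.tsv", sep="\t", index_label="cluster")
    if "targets" in out:
        out["targets"].to_csv(out_dir / "target_pairs.tsv", sep="\t", index=False)
    if "enrichment" in out:
        out["enrichment"].to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    with open(out_dir / "temporal_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    write_manifest(out_dir, cfg, inputs)
    out["report"] = report
    return out
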