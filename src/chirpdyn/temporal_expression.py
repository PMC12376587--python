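"""Time-course transcriptome analytics.

Standardizes FPKM profiles, selects dynamically expressed transcripts,
soft-clusters temporal profiles with fuzzy c-means, flags clusters with a
single-timepoint up/down pattern, predicts lncRNA targets by 100-kb
co-localization and timepoint co-expression, and scores term enrichment
with the hypergeometric upper tail plus Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .genome_io import ExpressionMatrix, GeneModel
from .rank_stats import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DynamicSelectParams:
    logfc_threshold: float = 0.75  # absolute log2 FC vs the reference timepoint
    pseudo_fpkm: float = 0.1

    def __post_init__(self) -> None:
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be > 0")


@dataclass(frozen=True)
class ClusterParams:
    k: int
    fuzzifier: float = 1.5
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


@dataclass
class ClusterResult:
    transcript_ids: list[str]
    membership: np.ndarray  # (n, k), rows sum to 1
    centroids: np.ndarray  # (k, n_timepoints), standardized units
    objective: float

    def __post_init__(self) -> None:
        if np.any(self.membership < -1e-12) or np.any(self.membership > 1 + 1e-12):
            raise ValueError("memberships out of [0, 1]")
        if not np.allclose(self.membership.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.membership, axis=1)


@dataclass(frozen=True)
class TargetParams:
    colocal_window: int = 100_000
    coexpr_min_abs_r: float = 0.9

    def __post_init__(self) -> None:
        if self.colocal_window <= 0:
            raise ValueError("colocal_window must be > 0")
        if not (0 < self.coexpr_min_abs_r <= 1):
            raise ValueError("coexpr_min_abs_r must be in (0, 1]")


# ---------------------------------------------------------------------------
# standardization and dynamic selection


def standardize(df: pd.DataFrame, min_shift: bool = False) -> pd.DataFrame:
    """Per-row z-score (population SD, ddof 0); zero-variance rows dropped.

    With ``min_shift`` the row minimum is additionally subtracted so the
    lowest standardized value is 0 while the SD stays 1.
    """
    values = df.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all rows have zero variance")
    if (~keep).sum():
        log.info("standardize: dropped %d zero-variance rows", int((~keep).sum()))
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[keep, None]
    if min_shift:
        z = z - z.min(axis=1, keepdims=True)
    return pd.DataFrame(z, index=df.index[keep], columns=df.columns)


def select_dynamic(
    df: pd.DataFrame, params: DynamicSelectParams = DynamicSelectParams()
) -> pd.Index:
    """Transcripts whose |log2 FC| vs the first (reference) timepoint
    exceeds the threshold at some timepoint. Columns must be timepoint-
    ordered with the reference first."""
    values = df.to_numpy(dtype=float)
    ref = values[:, [0]]
    logfc = np.log2((values + params.pseudo_fpkm) / (ref + params.pseudo_fpkm))
    keep = np.abs(logfc).max(axis=1) > params.logfc_threshold
    return df.index[keep]


# ---------------------------------------------------------------------------
# fuzzy c-means


def soft_kmeans(df: pd.DataFrame, params: ClusterParams) -> ClusterResult:
    """Fuzzy c-means on standardized temporal profiles.

    Memberships u_ij are proportional to (1/d_ij^2)^(1/(m-1)) with
    Euclidean distance; centroids are u^m-weighted means. Restarts use
    k-means++-style seeding (spreads initial centroids, never duplicates a
    point) and the best of ``n_restarts`` runs by the objective
    sum u^m d^2 is returned; everything is a pure function of
    (data, params.seed).
    """
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds {n} rows")
    rng = np.random.default_rng(params.seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(params.n_restarts):
        centroids = _kmeanspp_init(x, params.k, rng)
        membership = _fcm_memberships(x, centroids, params.fuzzifier)
        for _ in range(params.max_iter):
            um = membership**params.fuzzifier
            new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
            shift = float(np.abs(new_centroids - centroids).max())
            centroids = new_centroids
            membership = _fcm_memberships(x, centroids, params.fuzzifier)
            if shift < params.tol:
                break
        d2 = cdist(x, centroids, "sqeuclidean")
        obj = float((membership**params.fuzzifier * d2).sum())
        if best is None or obj < best[0]:
            best = (obj, membership, centroids)
    obj, membership, centroids = best
    return ClusterResult(list(df.index), membership, centroids, obj)


def _kmeanspp_init(x: np.ndarray, k: int, rng) -> np.ndarray:
    n = x.shape[0]
    idx = [int(rng.integers(n))]
    d2 = ((x - x[idx[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:  # fewer distinct points than k: fall back to uniform
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, ((x - x[idx[-1]]) ** 2).sum(axis=1))
    return x[idx].copy()


def _fcm_memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(x, centroids, "sqeuclidean")
    zero = d2 < 1e-300
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():  # point sits on a centroid: all mass there
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    w = d2[rest] ** (-1.0 / (m - 1.0))
    u[rest] = w / w.sum(axis=1, keepdims=True)
    return u


def select_stage_specific(
    result: ClusterResult,
    timepoints,
    min_margin: float = 0.5,
) -> list[dict]:
    """Clusters whose centroid has one isolated extremum.

    A cluster qualifies when the largest |centroid value| exceeds every
    other timepoint's |value| by at least ``min_margin`` SD units (unique
    extremum). Reports the extremum timepoint and direction.
    """
    timepoints = list(timepoints)
    out = []
    for ci, c in enumerate(result.centroids):
        mag = np.abs(c)
        i_star = int(np.argmax(mag))
        others = np.delete(mag, i_star)
        if others.size and mag[i_star] - others.max() >= min_margin:
            out.append(
                {
                    "cluster": ci,
                    "peak_time": timepoints[i_star],
                    "direction": "up" if c[i_star] > 0 else "down",
                    "margin": float(mag[i_star] - others.max()),
                }
            )
    return out


# ---------------------------------------------------------------------------
# lncRNA target prediction


def predict_targets(
    lnc_set: list[GeneModel],
    coding: list[GeneModel],
    expr: ExpressionMatrix | None,
    params: TargetParams = TargetParams(),
    condition: str | None = None,
) -> pd.DataFrame:
    """lncRNA -> coding-gene candidate pairs by co-localization (gap
    distance <= colocal_window on the same chromosome) and co-expression
    (|Pearson r| over timepoints >= coexpr_min_abs_r).

    Pairs with missing expression rows are evaluated on co-localization
    only and flagged. The evidence column is one of colocal / coexpr / both.
    """
    frame = None
    if expr is not None:
        cond = condition or expr.conditions()[0]
        frame = expr.condition_frame(cond)
    records = []
    for lnc in lnc_set:
        for cg in coding:
            gap = lnc.interval.gap_to(cg.interval)
            colocal = gap is not None and gap <= params.colocal_window
            r = np.nan
            if (
                frame is not None
                and lnc.gene_id in frame.index
                and cg.gene_id in frame.index
            ):
                a = frame.loc[lnc.gene_id].to_numpy(dtype=float)
                b = frame.loc[cg.gene_id].to_numpy(dtype=float)
                if a.std() > 0 and b.std() > 0:
                    r = float(np.corrcoef(a, b)[0, 1])
            coexpr = bool(np.abs(r) >= params.coexpr_min_abs_r) if np.isfinite(r) else False
            if not (colocal or coexpr):
                continue
            evidence = "both" if (colocal and coexpr) else ("colocal" if colocal else "coexpr")
            records.append(
                {
                    "lncRNA": lnc.gene_id,
                    "coding_gene": cg.gene_id,
                    "gap_bp": gap if gap is not None else -1,
                    "pearson_r": r,
                    "expression_missing": not np.isfinite(r),
                    "evidence": evidence,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "lncRNA",
            "coding_gene",
            "gap_bp",
            "pearson_r",
            "expression_missing",
            "evidence",
        ],
    )


# ---------------------------------------------------------------------------
# enrichment and DEG filtering


def hypergeom_enrich(
    target_genes,
    universe,
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per term with BH adjustment.

    term_map maps term id -> set of genes carrying the term. p_raw is
    P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K the
    universe genes with the term, n the target-set size and k the overlap.
    """
    targets = set(target_genes)
    uni = set(universe)
    if not targets <= uni:
        raise ValueError("target genes must be a subset of the universe")
    n, big_n = len(targets), len(uni)
    records = []
    for term, genes in sorted(term_map.items()):
        big_k = len(genes & uni)
        if big_k == 0:
            continue
        k = len(genes & targets)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        records.append(
            {"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p_raw": p}
        )
    df = pd.DataFrame(records, columns=["term", "k", "K", "n", "N", "p_raw"])
    if len(df):
        df["p_adj"] = benjamini_hochberg(df["p_raw"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df


def deg_filter(
    stats_table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression filter: |log2fc| >= 1 (inclusive) and
    padj < 0.05 (exclusive), on a table with log2fc and padj columns."""
    for col in ("log2fc", "padj"):
        if col not in stats_table.columns:
            raise ValueError(f"missing column {col!r}")
    if ((stats_table["padj"] < 0) | (stats_table["padj"] > 1)).any():
        raise ValueError("padj values outside [0, 1]")
    mask = (stats_table["log2fc"].abs() >= min_abs_log2fc) & (
        stats_table["padj"] < max_padj
    )
    return stats_table[mask]
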