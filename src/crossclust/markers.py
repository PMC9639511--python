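"""One-vs-rest differential expression per cluster.

Tie-corrected Wilcoxon rank-sum (normal approximation, no continuity
correction) plus an average log fold change computed on de-logged
normalized means with a pseudocount.  Because each cluster is tested
against all remaining cells, the per-gene ranks over the full cell set
are shared across clusters and computed once.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .enrichment import bh_adjust
from .io_formats import MARKER_COLUMNS, ClusterLabels
from .preprocess import NormMatrix

__all__ = ["rank_sum_test", "average_log_fc", "find_markers", "find_all_markers"]

DEFAULT_MIN_PCT = 0.1
DEFAULT_LOGFC_THRESHOLD = 0.25


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Mann-Whitney U for group ``a``, tie-corrected z, two-sided normal p.

    mu = n1*n2/2; sigma^2 = (n1*n2/12) * [(n+1) - sum(t^3 - t)/(n*(n-1))]
    over tie groups of size t.  No continuity correction.  If every
    pooled value is identical (sigma = 0) returns z = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 observations (got {n1}, {n2})")
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u, 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return u, z, p


def average_log_fc(in_values: Sequence[float], out_values: Sequence[float],
                   pseudocount: float = 1.0, base: str = "e") -> float:
    """log(mean(expm1(in)) + eps) - log(mean(expm1(out)) + eps).

    Natural log by default; ``base="2"`` divides by ln 2 (the newer
    toolkit convention, kept as an option).
    """
    in_values = np.asarray(in_values, dtype=float)
    out_values = np.asarray(out_values, dtype=float)
    if in_values.size == 0 or out_values.size == 0:
        raise ValueError("both groups must be non-empty")
    lfc = math.log(np.expm1(in_values).mean() + pseudocount) - \
        math.log(np.expm1(out_values).mean() + pseudocount)
    if base == "2":
        lfc /= math.log(2.0)
    elif base != "e":
        raise ValueError(f"base must be 'e' or '2', got {base!r}")
    return lfc


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row of a genes x cells matrix."""
    xs = np.sort(x, axis=1)
    out = np.zeros(x.shape[0])
    for i, row in enumerate(xs):
        starts = np.flatnonzero(np.r_[True, row[1:] != row[:-1]])
        t = np.diff(np.r_[starts, row.size]).astype(float)
        out[i] = float(np.sum(t**3 - t))
    return out


class _RankCache:
    """Global per-gene ranks and tie terms, shared by all one-vs-rest tests."""

    def __init__(self, values: np.ndarray):
        self.values = values
        self.ranks = rankdata(values, axis=1)
        self.tie_terms = _tie_terms(values)
        self.nonzero = values > 0
        self.expm1 = np.expm1(values)


def _cluster_stats(cache: _RankCache, mask: np.ndarray, pseudocount: float,
                   base: str) -> pd.DataFrame:
    n = mask.size
    n1 = int(mask.sum())
    n2 = n - n1
    r1 = cache.ranks[:, mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - cache.tie_terms / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, (u - n1 * n2 / 2.0) / np.sqrt(sigma2), 0.0)
    p = np.where(sigma2 > 0, np.minimum(1.0, 2.0 * norm.sf(np.abs(z))), 1.0)
    mean_in = cache.expm1[:, mask].mean(axis=1)
    mean_out = cache.expm1[:, ~mask].mean(axis=1)
    lfc = np.log(mean_in + pseudocount) - np.log(mean_out + pseudocount)
    if base == "2":
        lfc = lfc / math.log(2.0)
    pct_in = cache.nonzero[:, mask].mean(axis=1)
    pct_out = cache.nonzero[:, ~mask].mean(axis=1)
    return pd.DataFrame({"avg_logFC": lfc, "U": u, "z": z, "p": p,
                         "pct_in": pct_in, "pct_out": pct_out})


def _finalize(df: pd.DataFrame, cluster: str, genes: Sequence[str],
              keep: np.ndarray) -> pd.DataFrame:
    sub = df.loc[keep].copy()
    sub["gene"] = [genes[i] for i in np.flatnonzero(keep)]
    sub["cluster"] = cluster
    sub["padj"] = bh_adjust(sub["p"].to_numpy()) if len(sub) else np.array([])
    sub["_abs_lfc"] = sub["avg_logFC"].abs()
    sub = sub.sort_values(["p", "_abs_lfc", "gene"],
                          ascending=[True, False, True], kind="mergesort")
    sub = sub.drop(columns="_abs_lfc").reset_index(drop=True)
    return sub[MARKER_COLUMNS]


def _cluster_mask(norm: NormMatrix, labels: ClusterLabels, cluster: str) -> np.ndarray:
    if cluster not in labels.clusters:
        raise ValueError(f"unknown cluster {cluster!r}")
    mask = np.fromiter((labels.assignment.get(c) == cluster for c in norm.cells),
                       dtype=bool, count=len(norm.cells))
    if mask.sum() < 2:
        raise ValueError(f"cluster {cluster!r} has fewer than 2 cells")
    if (~mask).sum() < 2:
        raise ValueError(f"rest group for cluster {cluster!r} has fewer than 2 cells")
    return mask


def _markers_from_cache(cache: _RankCache, genes: list[str], mask: np.ndarray,
                        cluster: str, min_pct: float, logfc_threshold: float,
                        mode: str, pseudocount: float, base: str) -> pd.DataFrame:
    stats = _cluster_stats(cache, mask, pseudocount, base)
    expressed = cache.nonzero.any(axis=1)
    if mode == "full":
        keep = expressed
    elif mode == "filtered":
        keep = (expressed
                & (np.maximum(stats["pct_in"], stats["pct_out"]) >= min_pct).to_numpy()
                & (stats["avg_logFC"].abs() >= logfc_threshold).to_numpy())
        # BH spans only the genes actually tested
        stats = stats.copy()
    else:
        raise ValueError(f"mode must be 'filtered' or 'full', got {mode!r}")
    return _finalize(stats, cluster, genes, keep)


def find_markers(norm: NormMatrix, labels: ClusterLabels, cluster: str, *,
                 min_pct: float = DEFAULT_MIN_PCT,
                 logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
                 mode: str = "filtered", pseudocount: float = 1.0,
                 base: str = "e") -> pd.DataFrame:
    """Marker table for one cluster versus all remaining cells.

    ``filtered`` mode excludes genes failing the detection-fraction and
    fold-change prefilters before testing (BH spans tested genes only);
    ``full`` mode forces both thresholds to zero and tests every gene
    with at least one nonzero value, as required for complete ranked
    lists.
    """
    mask = _cluster_mask(norm, labels, cluster)
    cache = _RankCache(np.asarray(norm.values.todense()))
    return _markers_from_cache(cache, norm.genes, mask, cluster,
                               min_pct, logfc_threshold, mode, pseudocount, base)


def find_all_markers(norm: NormMatrix, labels: ClusterLabels, *,
                     min_pct: float = DEFAULT_MIN_PCT,
                     logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
                     mode: str = "filtered", pseudocount: float = 1.0,
                     base: str = "e") -> pd.DataFrame:
    """Concatenated marker tables for every cluster (ranks computed once)."""
    cache = _RankCache(np.asarray(norm.values.todense()))
    frames = []
    for cluster in labels.clusters:
        mask = _cluster_mask(norm, labels, cluster)
        frames.append(_markers_from_cache(cache, norm.genes, mask, cluster,
                                          min_pct, logfc_threshold, mode,
                                          pseudocount, base))
    return pd.concat(frames, ignore_index=True)
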