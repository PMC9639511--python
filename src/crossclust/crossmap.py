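"""Ortholog-mapped gene sets and signed-p ranked lists.

Source-cluster marker tables become gene sets in the target-species
namespace: walking each cluster's positive markers in significance
order, a source gene is consumed only if it has at least one ortholog,
and selection stops after ``top_n`` such mapped genes.  Target-cluster
marker tables (full mode) become ranked lists scored either by
signedP = sign(avg_logFC) * -log10(p) or by avg_logFC directly.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection, OrthologTable, RankedList

__all__ = ["build_gene_sets", "build_ranked_list", "DEFAULT_TOP_N", "DEFAULT_P_FLOOR"]

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 100
DEFAULT_P_FLOOR = 1e-300


def _sorted_cluster_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["_abs_lfc"] = out["avg_logFC"].abs()
    out = out.sort_values(["p", "_abs_lfc", "gene"],
                          ascending=[True, False, True], kind="mergesort")
    return out.drop(columns="_abs_lfc")


def build_gene_sets(source_markers: pd.DataFrame, orthologs: OrthologTable,
                    top_n: int = DEFAULT_TOP_N, *,
                    map_during_selection: bool = True) -> GeneSetCollection:
    """One target-namespace gene set per source cluster.

    Only positive-logFC markers are used.  With ``map_during_selection``
    (the default) the walk keeps selecting until ``top_n`` mapped source
    genes have been consumed; with ``False`` the top ``top_n`` markers
    are taken first and then mapped (the alternative reading).
    One-to-many orthologs expand to all their targets; duplicates are
    collapsed keeping first-seen order.  Clusters whose set comes out
    empty are omitted with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mapping = orthologs.source_to_targets()
    sets: dict[str, list[str]] = {}
    for cluster, table in source_markers.groupby("cluster", sort=False):
        table = _sorted_cluster_table(table[table["avg_logFC"] > 0])
        members: list[str] = []
        seen: set[str] = set()
        consumed = 0
        for gene in table["gene"]:
            targets = mapping.get(gene)
            if map_during_selection:
                if targets is None:
                    continue
                consumed += 1
            else:
                consumed += 1
                if targets is None:
                    targets = []
            for t in targets or []:
                if t not in seen:
                    seen.add(t)
                    members.append(t)
            if consumed >= top_n:
                break
        if members:
            sets[str(cluster)] = members
        else:
            logger.warning("cluster %s: no mappable positive markers; set omitted", cluster)
    return GeneSetCollection(sets=sets)


def build_ranked_list(target_markers: pd.DataFrame, metric: str = "signedP",
                      p_floor: float = DEFAULT_P_FLOOR) -> RankedList:
    """Ranked list for one target cluster from a full-mode marker table.

    signedP = sign(avg_logFC) * -log10(max(p, p_floor)); genes with
    avg_logFC exactly 0 score 0.  Ordering is score descending with
    gene-id ascending tie-break.
    """
    if metric not in ("signedP", "avg_logFC"):
        raise ValueError(f"metric must be 'signedP' or 'avg_logFC', got {metric!r}")
    if not 0 < p_floor <= 1:
        raise ValueError("p_floor must lie in (0, 1]")
    genes = target_markers["gene"].tolist()
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes)[pd.Series(genes).duplicated()].iloc[0]
        raise ValueError(f"duplicate gene in marker table: {dup!r}")
    if metric == "signedP":
        lfc = target_markers["avg_logFC"].to_numpy(dtype=float)
        p = np.maximum(target_markers["p"].to_numpy(dtype=float), p_floor)
        scores = np.sign(lfc) * (-np.log10(p))
        scores = np.where(lfc == 0.0, 0.0, scores)
    else:
        scores = target_markers["avg_logFC"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite ranking scores")
    return RankedList.from_scores(zip(genes, scores), metric=metric)
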